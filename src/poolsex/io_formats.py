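"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: every input keeps its native convention at the file
boundary (VCF and VarScan copynumber are 1-based, BED is 0-based half-open);
the in-memory interval representation is uniformly 0-based half-open, and
the functions here are the only place offsets are applied.  SNP positions
(:class:`PooledSiteCount.pos`) stay 1-based, as printed in VCF and in the
sync-style table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

SYNC_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "pool1_ref", "pool1_alt", "pool2_ref", "pool2_alt",
]

#: VarScan copynumber column order expected by :func:`read_varscan_segments`
#: (extra trailing columns such as gc_content are ignored).
VARSCAN_COLUMNS = [
    "chrom", "chr_start", "chr_stop", "num_positions",
    "normal_depth", "tumor_depth", "log2_ratio",
]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class PooledSiteCount:
    """One biallelic site with ref/alt read counts in two pools.

    By convention pool1 is the heterogametic (XY male) pool and pool2 the
    homogametic (XX female) pool; detector parameters can swap the roles
    for WZ systems.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    pool1_ref: int
    pool1_alt: int
    pool2_ref: int
    pool2_alt: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be one of {BASES}: "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref equals alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        for name in ("pool1_ref", "pool1_alt", "pool2_ref", "pool2_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def pool1_depth(self) -> int:
        return self.pool1_ref + self.pool1_alt

    @property
    def pool2_depth(self) -> int:
        return self.pool2_ref + self.pool2_alt


@dataclass(frozen=True)
class GapInterval:
    """An assembly gap, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class VarScanSegment:
    """A VarScan copynumber row; start/end 1-based inclusive as in the file."""

    chrom: str
    start: int
    end: int
    n_positions: int
    depth1: float
    depth2: float
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment end < start at {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")

    @property
    def interval(self) -> tuple[int, int]:
        """The segment as a 0-based half-open interval."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class Pfm:
    """A position frequency matrix, counts ordered A,C,G,T by row."""

    matrix_id: str
    name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"PFM {self.matrix_id}: counts must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"PFM {self.matrix_id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"PFM {self.matrix_id}: column with non-positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# sync-style table


def read_sync_table(path: str | Path) -> list[PooledSiteCount]:
    """Read the tab-separated pooled-count table (documented header order)."""
    records: list[PooledSiteCount] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SYNC_COLUMNS:
            raise FormatError(
                f"{path}: bad header {header!r}; expected {SYNC_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(SYNC_COLUMNS):
                raise FormatError(
                    f"{path}: expected {len(SYNC_COLUMNS)} columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref, alt, *count_s = fields
            try:
                pos = int(pos_s)
                counts = [int(c) for c in count_s]
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer field at line {lineno}: {exc}") from exc
            if ref == alt:
                raise FormatError(f"{path}: ref equals alt at line {lineno}")
            try:
                rec = PooledSiteCount(chrom, pos, ref, alt, *counts)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise FormatError(f"{path}: duplicate site {key} at line {lineno}")
            seen.add(key)
            records.append(rec)
    return records


def write_sync_table(records: Iterable[PooledSiteCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SYNC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.pool1_ref}\t{r.pool1_alt}\t{r.pool2_ref}\t{r.pool2_alt}\n"
            )


# ---------------------------------------------------------------------------
# VCF


class PooledVcfResult(NamedTuple):
    records: list[PooledSiteCount]
    n_skipped: int


def read_pooled_vcf(
    path: str | Path, pool1_sample: str, pool2_sample: str
) -> PooledVcfResult:
    """Read biallelic SNPs with per-pool allelic depths (AD) from a VCF.

    Multiallelic records and indels are skipped; the skip count is returned
    alongside the records and logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (pool1_sample, pool2_sample):
        if name not in samples:
            raise FormatError(f"{path}: sample {name!r} not in VCF (has {samples})")
    i1 = samples.index(pool1_sample)
    i2 = samples.index(pool2_sample)

    records: list[PooledSiteCount] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in BASES or var.ALT[0] not in BASES:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record {var.CHROM}:{var.POS} lacks AD")
        records.append(
            PooledSiteCount(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                pool1_ref=int(ad[i1][0]),
                pool1_alt=int(ad[i1][1]),
                pool2_ref=int(ad[i2][0]),
                pool2_alt=int(ad[i2][1]),
            )
        )
    if n_skipped:
        log.info("read_pooled_vcf: skipped %d multiallelic/indel records", n_skipped)
    return PooledVcfResult(records, n_skipped)


# ---------------------------------------------------------------------------
# JASPAR PFM text


def read_jaspar_pfm(path: str | Path) -> list[Pfm]:
    """Parse a JASPAR 2016 text file (``>ID name`` then four bracketed rows).

    Rows may appear in any order in the file; counts are returned in A,C,G,T
    row order.  Rows of unequal length are a hard error naming the motif.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse JASPAR file: {exc}") from exc
    out: list[Pfm] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        try:
            out.append(Pfm(matrix_id=m.matrix_id or m.name, name=m.name, counts=counts))
        except ValueError as exc:
            raise FormatError(f"{path}: motif {m.matrix_id}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# BED gaps and VarScan segments


def read_bed_gaps(path: str | Path) -> list[GapInterval]:
    """Read BED3 assembly gaps; overlapping/duplicate lines are merged with a warning."""
    raw: list[GapInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: expected >= 3 BED columns at line {lineno}")
            try:
                raw.append(GapInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    merged = merge_gaps(raw)
    if len(merged) != len(raw):
        log.warning(
            "%s: merged %d overlapping/duplicate gap lines into %d intervals",
            path, len(raw), len(merged),
        )
    return merged


def merge_gaps(gaps: Sequence[GapInterval]) -> list[GapInterval]:
    """Merge overlapping or book-ended gap intervals per chromosome."""
    out: list[GapInterval] = []
    by_chrom: dict[str, list[GapInterval]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for g in ivs[1:]:
            if g.start <= cur_e:
                cur_e = max(cur_e, g.end)
            else:
                out.append(GapInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = g.start, g.end
        out.append(GapInterval(chrom, cur_s, cur_e))
    return out


def read_varscan_segments(path: str | Path) -> list[VarScanSegment]:
    """Read a VarScan copynumber TSV (see :data:`VARSCAN_COLUMNS`)."""
    out: list[VarScanSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chrom":
                continue  # optional header
            if len(fields) < 7:
                raise FormatError(f"{path}: expected >= 7 columns at line {lineno}")
            try:
                out.append(
                    VarScanSegment(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        n_positions=int(fields[3]),
                        depth1=float(fields[4]),
                        depth2=float(fields[5]),
                        log2_ratio=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_varscan_segments(segments: Iterable[VarScanSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARSCAN_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_positions}\t"
                f"{s.depth1:.2f}\t{s.depth2:.2f}\t{s.log2_ratio:.4f}\n"
            )


# ---------------------------------------------------------------------------
# generic results writer


def write_results_tsv(
    frame: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write a result table with deterministic column order and fixed
    6-decimal float formatting; missing values are written as ``NA``."""
    if columns is not None:
        frame = frame.loc[:, list(columns)]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")
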