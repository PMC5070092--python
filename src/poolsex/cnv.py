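"""Conserved copy-number variants across n depth comparisons.

Input segments are VarScan-copynumber-style log2 depth-ratio intervals.
A segment is a directed CNV call when its |log2 ratio| reaches the amp or
del threshold (0.2 by default, inclusive).  A *conserved* CNV is a maximal
genomic interval covered in every comparison by at least one
same-direction call; the reported interval is the intersection of the
covering segments, which equals the per-base rule "a base is conserved iff
it is covered, same-direction, in all tracks".  ``min_support`` relaxes
"all" to "at least k" comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GapInterval, VarScanSegment, merge_gaps

AMP = "AMP"
DEL = "DEL"


@dataclass(frozen=True)
class DirectedSegment:
    """A thresholded CNV call, 0-based half-open."""

    chrom: str
    start: int
    end: int
    direction: str  # AMP | DEL
    log2_ratio: float
    source_id: str


@dataclass(frozen=True)
class ConservedCnv:
    chrom: str
    start: int
    end: int
    direction: str
    support: int
    source_ids: tuple[str, ...]

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def threshold_segments(
    segments: Sequence[VarScanSegment],
    amp_threshold: float = 0.2,
    del_threshold: float = 0.2,
    track_label: str = "t",
) -> list[DirectedSegment]:
    """Keep segments whose log2 ratio reaches a threshold (inclusive)."""
    if amp_threshold < 0 or del_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    out: list[DirectedSegment] = []
    for i, seg in enumerate(segments):
        if seg.log2_ratio >= amp_threshold:
            direction = AMP
        elif seg.log2_ratio <= -del_threshold:
            direction = DEL
        else:
            continue
        start, end = seg.interval
        out.append(
            DirectedSegment(
                chrom=seg.chrom, start=start, end=end, direction=direction,
                log2_ratio=seg.log2_ratio, source_id=f"{track_label}:{i}",
            )
        )
    return out


def conserved_cnvs(
    tracks: Sequence[Sequence[DirectedSegment]],
    min_support: int | None = None,
) -> list[ConservedCnv]:
    """Maximal intervals supported same-direction in >= min_support tracks
    (default: all of them).  Output sorted, non-overlapping per direction."""
    n = len(tracks)
    if n < 2:
        raise ValueError("need at least 2 comparisons")
    if min_support is None:
        min_support = n
    if not (1 <= min_support <= n):
        raise ValueError("min_support out of range")

    out: list[ConservedCnv] = []
    for direction in (AMP, DEL):
        keys = sorted(
            {seg.chrom for track in tracks for seg in track if seg.direction == direction}
        )
        for chrom in keys:
            per_track = [
                [s for s in track if s.chrom == chrom and s.direction == direction]
                for track in tracks
            ]
            bounds = sorted(
                {s.start for segs in per_track for s in segs}
                | {s.end for segs in per_track for s in segs}
            )
            run_start = None
            run_sources: set[str] = set()
            run_support = 0
            for lo, hi in zip(bounds, bounds[1:]):
                covering = [
                    [s for s in segs if s.start <= lo and s.end >= hi]
                    for segs in per_track
                ]
                support = sum(1 for c in covering if c)
                if support >= min_support:
                    if run_start is None:
                        run_start, run_support = lo, support
                    run_support = min(run_support, support)
                    run_sources.update(s.source_id for c in covering for s in c)
                elif run_start is not None:
                    out.append(
                        ConservedCnv(chrom, run_start, lo, direction,
                                     run_support, tuple(sorted(run_sources)))
                    )
                    run_start, run_sources, run_support = None, set(), 0
            if run_start is not None:
                out.append(
                    ConservedCnv(chrom, run_start, bounds[-1], direction,
                                 run_support, tuple(sorted(run_sources)))
                )
    out.sort(key=lambda c: (c.chrom, c.start, c.direction))
    return out


@dataclass
class CnvWindow:
    chrom: str
    start: int
    end: int
    n_cnvs: int
    effective_len: int
    excluded: bool  # entirely inside assembly gaps

    @property
    def density_per_mb(self) -> float | None:
        if self.excluded:
            return None
        return self.n_cnvs / (self.effective_len / 1e6)


def cnv_window_density(
    conserved: Sequence[ConservedCnv],
    window_size: int = 10_000,
    gaps: Sequence[GapInterval] = (),
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[CnvWindow]:
    """Per-window conserved-CNV counts with gap-excluded effective length.

    A CNV is counted once, in the window holding its midpoint; windows
    entirely inside gaps are flagged excluded (density undefined).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    merged = merge_gaps(gaps) if gaps else []
    gaps_by_chrom: dict[str, list[GapInterval]] = {}
    for g in merged:
        gaps_by_chrom.setdefault(g.chrom, []).append(g)

    lengths: dict[str, int] = dict(chrom_lengths or {})
    for c in conserved:
        if lengths.get(c.chrom, 0) < c.end:
            lengths[c.chrom] = c.end

    counts: dict[tuple[str, int], int] = {}
    for c in conserved:
        widx = int(c.midpoint // window_size)
        counts[(c.chrom, widx)] = counts.get((c.chrom, widx), 0) + 1

    out: list[CnvWindow] = []
    for chrom, length in lengths.items():
        n_windows = max(1, -(-length // window_size))
        for widx in range(n_windows):
            start = widx * window_size
            end = min(length, start + window_size)
            overlap = sum(
                max(0, min(end, g.end) - max(start, g.start))
                for g in gaps_by_chrom.get(chrom, ())
            )
            eff = (end - start) - overlap
            out.append(
                CnvWindow(chrom, start, end, counts.get((chrom, widx), 0),
                          eff, excluded=eff == 0)
            )
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def conserved_to_frame(conserved: Sequence[ConservedCnv]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom, "start": c.start, "end": c.end,
                "direction": c.direction, "support": c.support,
                "source_ids": ",".join(c.source_ids),
            }
            for c in conserved
        ],
        columns=["chrom", "start", "end", "direction", "support", "source_ids"],
    )
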