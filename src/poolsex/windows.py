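"""Fixed-window densities, enrichment calls and region comparisons.

Chromosomes are tiled with non-overlapping windows (10 kb by default)
anchored at coordinate 0; the trailing partial window is kept with its
true length.  A window is *enriched* when it contains at least
``min_snps`` sex-patterned SNPs (10 by default, inclusive).  Region
comparisons use two-sided Mann-Whitney U tests on per-window sex-patterned
SNP counts, with a Bonferroni-corrected significance threshold
(alpha/m, m = 12 comparisons by default, giving 0.004167).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io_formats import GapInterval, merge_gaps
from .sexsnp import SiteStats


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, as used in printed densities and alpha."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Region:
    """A named set of non-overlapping genomic intervals (0-based half-open)."""

    label: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple(tuple(iv) for iv in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in ivs:
            if start >= end:
                raise ValueError(f"region {self.label}: empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"region {self.label}: overlapping intervals on {chrom}")

    @property
    def length_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, coord: float) -> bool:
        """Membership of a 0-based coordinate (window midpoints may be half-integral)."""
        return any(c == chrom and s <= coord < e for c, s, e in self.intervals)

    @staticmethod
    def complement(
        chrom_lengths: Mapping[str, int],
        regions: Sequence["Region"],
        label: str = "rest_of_genome",
    ) -> "Region":
        """The rest of the genome: everything outside the named regions."""
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
        for region in regions:
            for chrom, start, end in region.intervals:
                if chrom in taken:
                    taken[chrom].append((start, end))
        out: list[tuple[str, int, int]] = []
        for chrom, length in chrom_lengths.items():
            cursor = 0
            for start, end in sorted(taken[chrom]):
                if start > cursor:
                    out.append((chrom, cursor, min(start, length)))
                cursor = max(cursor, end)
            if cursor < length:
                out.append((chrom, cursor, length))
        return Region(label, tuple(out))


@dataclass
class WindowSummary:
    chrom: str
    start: int
    end: int
    n_sex_patterned: int
    n_total_snps: int
    effective_len: int
    enriched: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class RegionSummary:
    region: Region
    mean_fst_polymorphic: float | None
    n_sex_patterned: int
    density_per_mb: float
    n_enriched_windows: int
    enriched_density_per_mb: float
    class_counts: dict[str, int] | None = None
    class_densities: dict[str, float] | None = None


def _gap_overlap(gaps_by_chrom: Mapping[str, list[GapInterval]], chrom: str,
                 start: int, end: int) -> int:
    total = 0
    for g in gaps_by_chrom.get(chrom, ()):
        total += max(0, min(end, g.end) - max(start, g.start))
    return total


def window_counts(
    stats: Sequence[SiteStats],
    window_size: int = 10_000,
    gaps: Sequence[GapInterval] = (),
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[WindowSummary]:
    """Tile each chromosome from 0 and count sites per window.

    A 1-based site position ``pos`` falls in window floor((pos-1)/size).
    Without explicit chromosome lengths, tiling extends to the last
    observed site (rounded up to a whole window).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    merged = merge_gaps(gaps) if gaps else []
    gaps_by_chrom: dict[str, list[GapInterval]] = {}
    for g in merged:
        gaps_by_chrom.setdefault(g.chrom, []).append(g)

    lengths: dict[str, int] = dict(chrom_lengths or {})
    for s in stats:
        need = s.pos  # pos is 1-based; window end must cover pos-1
        if lengths.get(s.chrom, 0) < need:
            if chrom_lengths is not None and s.chrom in chrom_lengths:
                raise ValueError(
                    f"site {s.chrom}:{s.pos} beyond declared chromosome length"
                )
            lengths[s.chrom] = need

    counts: dict[tuple[str, int], list[int]] = {}
    for s in stats:
        widx = (s.pos - 1) // window_size
        cell = counts.setdefault((s.chrom, widx), [0, 0])
        cell[1] += 1
        if s.is_sex_patterned:
            cell[0] += 1

    out: list[WindowSummary] = []
    for chrom, length in lengths.items():
        n_windows = max(1, -(-length // window_size))
        for widx in range(n_windows):
            start = widx * window_size
            end = min(length, start + window_size)
            n_sex, n_tot = counts.get((chrom, widx), (0, 0))
            eff = (end - start) - _gap_overlap(gaps_by_chrom, chrom, start, end)
            out.append(WindowSummary(chrom, start, end, n_sex, n_tot, eff))
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def call_enriched(
    windows: Sequence[WindowSummary], min_snps: int = 10
) -> list[WindowSummary]:
    """Flag windows with at least ``min_snps`` sex-patterned SNPs (inclusive)."""
    for w in windows:
        w.enriched = w.n_sex_patterned >= min_snps
    return list(windows)


def density_per_mb(count: int, length_bp: int) -> float:
    return round_half_up(count / (length_bp / 1e6), 2)


def summarize_region(
    stats: Sequence[SiteStats],
    windows: Sequence[WindowSummary],
    region: Region,
    annotations: Mapping[tuple[str, int], tuple[str, float | None]] | None = None,
) -> RegionSummary:
    """Counts, densities and mean F_ST for one region.

    mean F_ST averages per-site F_ST over all sites in the region where it
    is defined (polymorphic in the combined data), not only sex-patterned
    sites.  Optional annotations map (chrom, pos) to an effect label and a
    PROVEAN score; sex-patterned sites are then broken down into missense /
    deleterious (PROVEAN < -2.5) / synonymous classes.
    """
    if region.length_bp <= 0:
        raise ValueError(f"region {region.label} has zero length")
    in_region = [s for s in stats if region.contains(s.chrom, s.pos - 1)]
    fst_vals = [s.fst for s in in_region if s.fst is not None]
    mean_fst = float(np.mean(fst_vals)) if fst_vals else None
    sex_sites = [s for s in in_region if s.is_sex_patterned]
    n_sex = len(sex_sites)
    n_enriched = sum(
        1 for w in windows if w.enriched and region.contains(w.chrom, w.midpoint)
    )
    class_counts = class_densities = None
    if annotations is not None:
        class_counts = {"missense": 0, "deleterious": 0, "synonymous": 0}
        for s in sex_sites:
            ann = annotations.get((s.chrom, s.pos))
            if ann is None:
                continue
            effect, provean = ann
            if effect == "missense":
                class_counts["missense"] += 1
                if provean is not None and provean < -2.5:
                    class_counts["deleterious"] += 1
            elif effect == "synonymous":
                class_counts["synonymous"] += 1
        class_densities = {
            k: density_per_mb(v, region.length_bp) for k, v in class_counts.items()
        }
    return RegionSummary(
        region=region,
        mean_fst_polymorphic=mean_fst,
        n_sex_patterned=n_sex,
        density_per_mb=density_per_mb(n_sex, region.length_bp),
        n_enriched_windows=n_enriched,
        enriched_density_per_mb=density_per_mb(n_enriched, region.length_bp),
        class_counts=class_counts,
        class_densities=class_densities,
    )


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midrank ties).

    Exact null distribution when n_a + n_b <= 16 and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha: float = 0.05, m: int = 12) -> float:
    """Per-comparison significance threshold alpha/m, rounded to 6 decimals."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round_half_up(alpha / m, 6)


def compare_regions(
    windows: Sequence[WindowSummary],
    region_pairs: Sequence[tuple[Region, Region]],
    alpha: float = 0.05,
    m: int = 12,
) -> pd.DataFrame:
    """Mann-Whitney comparison of per-window sex-patterned SNP counts.

    A window belongs to a region when its midpoint falls inside it; the
    two regions of a pair must be disjoint.  Significance is at the
    Bonferroni-corrected threshold alpha/m.
    """
    threshold = bonferroni_alpha(alpha, m)
    rows = []
    for region_a, region_b in region_pairs:
        for chrom, start, end in region_a.intervals:
            for c2, s2, e2 in region_b.intervals:
                if chrom == c2 and start < e2 and s2 < end:
                    raise ValueError(
                        f"regions {region_a.label} and {region_b.label} overlap"
                    )
        counts_a = [w.n_sex_patterned for w in windows
                    if region_a.contains(w.chrom, w.midpoint)]
        counts_b = [w.n_sex_patterned for w in windows
                    if region_b.contains(w.chrom, w.midpoint)]
        u, p = mann_whitney_u(counts_a, counts_b)
        rows.append(
            {
                "region_a": region_a.label,
                "region_b": region_b.label,
                "n_windows_a": len(counts_a),
                "n_windows_b": len(counts_b),
                "U": u,
                "p": p,
                "alpha_corrected": threshold,
                "significant": p < threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_a", "region_b", "n_windows_a", "n_windows_b",
                 "U", "p", "alpha_corrected", "significant"],
    )


def windows_to_frame(windows: Sequence[WindowSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_sex_patterned": w.n_sex_patterned,
                "n_total_snps": w.n_total_snps,
                "effective_len": w.effective_len,
                "enriched": int(w.enriched),
            }
            for w in windows
        ],
        columns=["chrom", "start", "end", "n_sex_patterned", "n_total_snps",
                 "effective_len", "enriched"],
    )
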