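"""Cross-species shared sex-patterned SNPs and the null expectation.

Both species are mapped to one reference, so positions are directly
comparable.  At each position sex-patterned in both species the inferred
X/Y alleles are compared and the site is classified as CONSERVED (same X,
same Y), SWITCHED (X and Y exchanged between lineages — alternative
lineage sorting of an ancestral polymorphism), SAME_X_DIFF_Y (X retained,
Y replaced) or OTHER; the classes partition the intersection.  The null
expectation for the shared count in a region of length L is
(n_a/L)(n_b/L)L = n_a*n_b/L, i.e. independent placement of each species'
sex-patterned SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .sexsnp import SiteStats
from .windows import Region, round_half_up

CONSERVED = "CONSERVED"
SWITCHED = "SWITCHED"
SAME_X_DIFF_Y = "SAME_X_DIFF_Y"
OTHER = "OTHER"


@dataclass(frozen=True)
class SharedSnpRecord:
    chrom: str
    pos: int
    x_a: str
    y_a: str
    x_b: str
    y_b: str
    consistency_class: str


@dataclass(frozen=True)
class NullExpectation:
    n_a: int
    n_b: int
    region_length_bp: int

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.region_length_bp

    @property
    def expected_rounded(self) -> float:
        return round_half_up(self.expected, 2)


def infer_xy_alleles(stats: SiteStats) -> tuple[str, str]:
    """X = allele fixed/near-fixed in the homogametic pool; Y = the other.

    Only valid on sex-patterned sites.  Works from the recorded alleles
    when the detector stored them, else from the homogametic alt frequency.
    """
    if not stats.is_sex_patterned:
        raise ValueError(
            f"X/Y alleles are only defined for sex-patterned sites "
            f"({stats.chrom}:{stats.pos} is not)"
        )
    if stats.x_allele is not None and stats.y_allele is not None:
        return stats.x_allele, stats.y_allele
    if stats.p_hom is None:
        raise ValueError("site lacks homogametic-pool frequency")
    if stats.p_hom < 0.5:
        return stats.site.ref_allele, stats.site.alt_allele
    return stats.site.alt_allele, stats.site.ref_allele


def classify_alleles(x_a: str, y_a: str, x_b: str, y_b: str) -> str:
    """Mutually exclusive classes checked in order CONSERVED, SWITCHED, SAME_X_DIFF_Y."""
    if x_a == x_b and y_a == y_b:
        return CONSERVED
    if x_a == y_b and y_a == x_b:
        return SWITCHED
    if x_a == x_b and y_a != y_b:
        return SAME_X_DIFF_Y
    return OTHER


def _check_sorted_stats(stats: Sequence[SiteStats], name: str) -> None:
    keys = [(s.chrom, s.pos) for s in stats]
    seen: set[str] = set()
    prev: tuple[str, int] | None = None
    for chrom, pos in keys:
        if prev is None or chrom != prev[0]:
            if chrom in seen:
                raise ValueError(f"{name}: input not sorted (chromosome {chrom})")
            seen.add(chrom)
        elif pos <= prev[1]:
            raise ValueError(f"{name}: input not sorted at {chrom}:{pos}")
        prev = (chrom, pos)


def intersect_and_classify(
    stats_a: Sequence[SiteStats], stats_b: Sequence[SiteStats]
) -> list[SharedSnpRecord]:
    """Shared sex-patterned positions with their X/Y consistency class."""
    _check_sorted_stats(stats_a, "species A")
    _check_sorted_stats(stats_b, "species B")
    sex_b = {
        (s.chrom, s.pos): s for s in stats_b if s.is_sex_patterned
    }
    out: list[SharedSnpRecord] = []
    for s_a in stats_a:
        if not s_a.is_sex_patterned:
            continue
        s_b = sex_b.get((s_a.chrom, s_a.pos))
        if s_b is None:
            continue
        x_a, y_a = infer_xy_alleles(s_a)
        x_b, y_b = infer_xy_alleles(s_b)
        out.append(
            SharedSnpRecord(
                chrom=s_a.chrom, pos=s_a.pos,
                x_a=x_a, y_a=y_a, x_b=x_b, y_b=y_b,
                consistency_class=classify_alleles(x_a, y_a, x_b, y_b),
            )
        )
    return out


def expected_shared(n_a: int, n_b: int, region_length_bp: int) -> NullExpectation:
    """Null expectation n_a * n_b / L for the shared count in a region."""
    if region_length_bp <= 0:
        raise ValueError("region length must be positive")
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    return NullExpectation(n_a=n_a, n_b=n_b, region_length_bp=region_length_bp)


def filter_by_region(
    records: Sequence[SharedSnpRecord], regions: Sequence[Region]
) -> tuple[dict[str, list[SharedSnpRecord]], dict[str, int]]:
    """Partition records by the first region containing them; leftovers go
    to ``"other"``.  Returns (partition, counts); counts sum to the total."""
    partition: dict[str, list[SharedSnpRecord]] = {r.label: [] for r in regions}
    partition["other"] = []
    for rec in records:
        for region in regions:
            if region.contains(rec.chrom, rec.pos - 1):
                partition[region.label].append(rec)
                break
        else:
            partition["other"].append(rec)
    counts = {label: len(rs) for label, rs in partition.items()}
    return partition, counts


def shared_to_frame(
    records: Sequence[SharedSnpRecord],
    region_of: Mapping[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos,
                "X_a": r.x_a, "Y_a": r.y_a, "X_b": r.x_b, "Y_b": r.y_b,
                "class": r.consistency_class,
                "region": (region_of or {}).get((r.chrom, r.pos), "other"),
            }
            for r in records
        ],
        columns=["chrom", "pos", "X_a", "Y_a", "X_b", "Y_b", "class", "region"],
    )
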