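"""Per-site sex-pattern classification and differentiation statistics.

A *sex-patterned* SNP is the pooled-data signature of a Y- (or W-) linked
variant: one allele fixed or nearly fixed in the homogametic-sex pool while
the other allele segregates at intermediate frequency (0.3-0.7 by default)
in the heterogametic-sex pool.  Alongside the classification, five per-site
differentiation statistics are computed for every evaluable position:

* F_ST  — pi-based estimator: per-pool pi with the n/(n-1) small-sample
  correction, pi_T from the summed counts, F_ST = (pi_T - pi_S)/pi_T.
* d_xy  — mean pairwise difference between one read from each pool,
  p_x(1-p_y) + p_y(1-p_x).
* d_a   — d_xy net of mean within-pool diversity, d_xy - (pi_x + pi_y)/2.
* Nei's D — -ln of the normalised genetic identity I; at alternatively
  fixed sites frequencies of 0/1 are clamped to 1/max_coverage so D stays
  finite.
* C_P   — half the L1 distance between the two pools' allele-frequency
  vectors: 0 = identical pools, 1 = disjoint allele support.

Undefined statistics (depth below 2, or pi_T = 0) are carried as ``None``
and written as ``NA``, never as 0, so downstream averages over polymorphic
sites can exclude them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import PooledSiteCount, write_results_tsv

log = logging.getLogger(__name__)

SITESTATS_COLUMNS = [
    "chrom", "pos", "ref", "alt", "p_het", "p_hom",
    "fst", "dxy", "da", "nei_d", "cp", "sex_patterned", "evaluated",
]


@dataclass(frozen=True)
class DetectorParams:
    """Thresholds of the sex-patterned SNP detector.

    het_low/het_high bound the candidate allele's frequency in the
    heterogametic pool (closed interval); homog_fixed_max is the maximum
    minor-allele frequency still counted as "nearly fixed" in the
    homogametic pool; min_allele_count applies to the candidate sex-linked
    allele's reads in the heterogametic pool; max_coverage sets the clamp
    for Nei's D at alternatively fixed sites.  heterogametic_pool selects
    which pool (1 or 2) is the heterogametic sex, so a WZ system is handled
    by swapping roles.
    """

    het_low: float = 0.3
    het_high: float = 0.7
    homog_fixed_max: float = 0.1
    min_depth: int = 10
    min_allele_count: int = 2
    max_coverage: int = 100
    heterogametic_pool: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.het_low < self.het_high <= 1):
            raise ValueError("need 0 <= het_low < het_high <= 1")
        if not (0 <= self.homog_fixed_max < self.het_low):
            raise ValueError("need 0 <= homog_fixed_max < het_low")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_coverage < 2:
            raise ValueError("max_coverage must be >= 2")
        if self.heterogametic_pool not in (1, 2):
            raise ValueError("heterogametic_pool must be 1 or 2")


@dataclass
class SiteStats:
    """Per-site frequencies, statistics and sex-pattern classification."""

    site: PooledSiteCount
    p_het: float | None = None  # alt-allele frequency, heterogametic pool
    p_hom: float | None = None  # alt-allele frequency, homogametic pool
    fst: float | None = None
    dxy: float | None = None
    da: float | None = None
    nei_d: float | None = None
    cp: float | None = None
    is_sex_patterned: bool = False
    evaluated: bool = False
    x_allele: str | None = field(default=None)
    y_allele: str | None = field(default=None)

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos


def _pool_counts(site: PooledSiteCount, params: DetectorParams) -> tuple[tuple[int, int], tuple[int, int]]:
    """Return ((het_ref, het_alt), (hom_ref, hom_alt))."""
    p1 = (site.pool1_ref, site.pool1_alt)
    p2 = (site.pool2_ref, site.pool2_alt)
    return (p1, p2) if params.heterogametic_pool == 1 else (p2, p1)


def compute_cp(freqs_het: Sequence[float], freqs_hom: Sequence[float]) -> float:
    """C_P = sum_i (1/2)|x_i - y_i| over a common allele set."""
    x = np.asarray(freqs_het, dtype=float)
    y = np.asarray(freqs_hom, dtype=float)
    if x.shape != y.shape:
        raise ValueError("allele-frequency vectors must cover the same allele set")
    for v, name in ((x, "het"), (y, "hom")):
        if not math.isclose(v.sum(), 1.0, abs_tol=1e-8):
            raise ValueError(f"{name} frequencies must sum to 1 (got {v.sum()})")
    return float(0.5 * np.abs(x - y).sum())


def _pi(ref: int, alt: int) -> float | None:
    """Per-pool nucleotide diversity with the n/(n-1) correction; None if depth < 2."""
    n = ref + alt
    if n < 2:
        return None
    p = alt / n
    return (n / (n - 1)) * 2.0 * p * (1.0 - p)


def compute_fst(site: PooledSiteCount, params: DetectorParams | None = None) -> float | None:
    """Per-site pi-based F_ST; None when undefined (depth < 2 or pi_T = 0).

    Because the small-sample correction differs between one pool (n/(n-1))
    and the pooled total (2n/(2n-1)), the raw estimator dips slightly below
    zero for near-identical pools; values are truncated to [0, 1].
    """
    params = params or DetectorParams()
    (het_ref, het_alt), (hom_ref, hom_alt) = _pool_counts(site, params)
    pi1 = _pi(het_ref, het_alt)
    pi2 = _pi(hom_ref, hom_alt)
    if pi1 is None or pi2 is None:
        return None
    pi_s = 0.5 * (pi1 + pi2)
    pi_t = _pi(het_ref + hom_ref, het_alt + hom_alt)
    if pi_t is None or pi_t == 0.0:
        return None
    return min(1.0, max(0.0, (pi_t - pi_s) / pi_t))


def compute_dxy_da(
    site: PooledSiteCount, params: DetectorParams | None = None
) -> tuple[float, float | None]:
    """(d_xy, d_a) for one site; d_a is None when either within-pool pi is undefined."""
    params = params or DetectorParams()
    (het_ref, het_alt), (hom_ref, hom_alt) = _pool_counts(site, params)
    n_het = het_ref + het_alt
    n_hom = hom_ref + hom_alt
    if n_het < 1 or n_hom < 1:
        raise ValueError("d_xy requires depth >= 1 in both pools")
    p_x = het_alt / n_het
    p_y = hom_alt / n_hom
    dxy = p_x * (1.0 - p_y) + p_y * (1.0 - p_x)
    pi_x = _pi(het_ref, het_alt)
    pi_y = _pi(hom_ref, hom_alt)
    da = None if pi_x is None or pi_y is None else dxy - 0.5 * (pi_x + pi_y)
    return dxy, da


def compute_nei_d(site: PooledSiteCount, params: DetectorParams | None = None) -> float:
    """Nei's standard genetic distance D = -ln I at one site.

    At alternatively fixed sites (I would be 0) frequencies 0 and 1 are
    replaced by 1/max_coverage and 1 - 1/max_coverage first, so D is
    finite and scales with the user's maximum coverage.
    """
    params = params or DetectorParams()
    (het_ref, het_alt), (hom_ref, hom_alt) = _pool_counts(site, params)
    n_het = het_ref + het_alt
    n_hom = hom_ref + hom_alt
    if n_het < 1 or n_hom < 1:
        raise ValueError("Nei's D requires depth >= 1 in both pools")
    x = np.array([het_ref / n_het, het_alt / n_het])
    y = np.array([hom_ref / n_hom, hom_alt / n_hom])
    if float(x @ y) == 0.0:  # alternatively fixed: clamp to keep D finite
        eps = 1.0 / params.max_coverage
        x = np.clip(x, eps, 1.0 - eps)
        y = np.clip(y, eps, 1.0 - eps)
    identity = float(x @ y) / math.sqrt(float(x @ x) * float(y @ y))
    return max(0.0, -math.log(identity))


def classify_site(site: PooledSiteCount, params: DetectorParams | None = None) -> SiteStats:
    """Classify one site; fills frequencies, flags and inferred X/Y alleles only.

    ``evaluated`` is False when either pool is below min_depth.  A site is
    sex-patterned when (a) one allele is at frequency >= 1 - homog_fixed_max
    in the homogametic pool, (b) the *other* allele's frequency in the
    heterogametic pool lies in [het_low, het_high], and (c) that allele has
    at least min_allele_count reads in the heterogametic pool.
    """
    params = params or DetectorParams()
    stats = SiteStats(site=site)
    (het_ref, het_alt), (hom_ref, hom_alt) = _pool_counts(site, params)
    n_het = het_ref + het_alt
    n_hom = hom_ref + hom_alt
    if n_het < params.min_depth or n_hom < params.min_depth:
        return stats
    stats.evaluated = True
    stats.p_het = het_alt / n_het
    stats.p_hom = hom_alt / n_hom

    # candidate X = major allele of the homogametic pool
    hom_major_is_ref = hom_ref >= hom_alt
    hom_major_freq = (hom_ref if hom_major_is_ref else hom_alt) / n_hom
    if hom_major_freq < 1.0 - params.homog_fixed_max:
        return stats
    # candidate Y = the other allele; frequency and count in the het pool
    y_count = het_alt if hom_major_is_ref else het_ref
    y_freq = y_count / n_het
    if params.het_low <= y_freq <= params.het_high and y_count >= params.min_allele_count:
        stats.is_sex_patterned = True
        stats.x_allele = site.ref_allele if hom_major_is_ref else site.alt_allele
        stats.y_allele = site.alt_allele if hom_major_is_ref else site.ref_allele
    return stats


def site_stats(site: PooledSiteCount, params: DetectorParams | None = None) -> SiteStats:
    """Classification plus all five differentiation statistics for one site."""
    params = params or DetectorParams()
    stats = classify_site(site, params)
    if not stats.evaluated:
        return stats
    stats.fst = compute_fst(site, params)
    stats.dxy, stats.da = compute_dxy_da(site, params)
    stats.nei_d = compute_nei_d(site, params)
    stats.cp = compute_cp(
        [1.0 - stats.p_het, stats.p_het], [1.0 - stats.p_hom, stats.p_hom]
    )
    return stats


def check_sorted(sites: Iterable[PooledSiteCount]) -> None:
    """Raise unless sites come in (chrom, pos) order with contiguous chromosome blocks."""
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen_chroms:
                raise ValueError(f"input not sorted: chromosome {s.chrom} not contiguous")
            seen_chroms.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, 0
        if s.pos <= prev_pos:
            raise ValueError(f"input not sorted at {s.chrom}:{s.pos}")
        prev_pos = s.pos


def scan_dataset(
    sites: Sequence[PooledSiteCount], params: DetectorParams | None = None
) -> list[SiteStats]:
    """One pass over a sorted dataset; returns one SiteStats per input site."""
    params = params or DetectorParams()
    check_sorted(sites)
    out = [site_stats(s, params) for s in sites]
    n_eval = sum(s.evaluated for s in out)
    n_sex = sum(s.is_sex_patterned for s in out)
    log.info(
        "scan_dataset: %d sites, %d evaluated, %d sex-patterned",
        len(out), n_eval, n_sex,
    )
    return out


# ---------------------------------------------------------------------------
# sitestats TSV round-trip


def stats_to_frame(stats: Sequence[SiteStats]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.site.ref_allele,
            "alt": s.site.alt_allele,
            "p_het": s.p_het,
            "p_hom": s.p_hom,
            "fst": s.fst,
            "dxy": s.dxy,
            "da": s.da,
            "nei_d": s.nei_d,
            "cp": s.cp,
            "sex_patterned": int(s.is_sex_patterned),
            "evaluated": int(s.evaluated),
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=SITESTATS_COLUMNS)


def write_sitestats(stats: Sequence[SiteStats], path: str | Path) -> None:
    write_results_tsv(stats_to_frame(stats), path)


def read_sitestats(path: str | Path) -> pd.DataFrame:
    """Read a sitestats TSV; NA becomes NaN.  X/Y alleles are re-derivable:
    X is the homogametic pool's major allele (ref if p_hom < 0.5 else alt)."""
    frame = pd.read_csv(path, sep="\t", na_values="NA")
    missing = set(SITESTATS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame
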