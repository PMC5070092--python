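"""Synthetic pooled-sequencing data with known truth.

The generative model mirrors the study design the detector targets: a
single family segregating an XY system, sequenced as one male and one
female pool.  Inside the sex-determination (SD) region, sex-patterned
sites carry a Y-linked allele that is absent from the female pool and sits
at exactly 0.5 at the chromosome level in the male pool (all males XY, so
n_males of 2*n_males male chromosomes carry the Y haplotype).  Background
polymorphism is shared between the pools with a frequency drawn from a
uniform folded spectrum {0.1, ..., 0.9}, snapped per pool to the k/(2n)
chromosome-count grid.  Read counts are binomial draws from the
chromosome-level frequencies at Poisson-distributed per-pool depth;
sequencing error is an optional per-read allele flip (off by default —
the detector's minimum-allele-count filter exists to absorb it).

A species pair shares an ancestral SD region whose sex-patterned sites are
partitioned into conserved, X/Y-switched and Y-replaced fates (partial
lineage sorting of Y alleles), the remainder being private to each species.

Copy-number tracks emulate VarScan copynumber output: true CNVs appear in
every comparison as same-direction segments of 100 bp-1 kb (longer events
are tiled), |log2 ratio| >= 0.2; noise segments appear in one track only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, PooledSiteCount, VarScanSegment

CATEGORY_SEX = "sex_patterned_Y"
CATEGORY_BACKGROUND = "background"
CATEGORY_MONO = "monomorphic"

SHARED_CONSERVED = "CONSERVED"
SHARED_SWITCHED = "SWITCHED"
SHARED_Y_REPLACED = "SAME_X_DIFF_Y"


@dataclass(frozen=True)
class SimConfig:
    """Design parameters of one simulated pooled-sequencing experiment.

    Defaults follow the emulated study: 21 males vs 22 females (one male
    excluded for ambiguous gonads), ~35x coverage per pool, and a
    sex-patterned site density of ~600/Mb inside the SD region over a
    ~2/kb background polymorphism rate.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"LG1": 1_000_000}
    )
    n_males: int = 21
    n_females: int = 22
    mean_coverage: float = 35.0
    sd_region: tuple[str, int, int] = ("LG1", 400_000, 600_000)  # 0-based half-open
    background_snp_rate: float = 2e-3
    sd_snp_rate: float = 6e-4
    monomorphic_rate: float = 0.0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("pool sizes must be >= 1")
        for name in ("background_snp_rate", "sd_snp_rate", "monomorphic_rate",
                     "seq_error_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        chrom, start, end = self.sd_region
        if chrom not in self.chrom_lengths:
            if self.sd_snp_rate > 0:
                raise ValueError(f"sd_region chromosome {chrom!r} not in chrom_lengths")
        elif not (0 <= start < end <= self.chrom_lengths[chrom]):
            if self.sd_snp_rate > 0 or start != end:
                raise ValueError("sd_region must lie within its chromosome")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int  # 1-based, matching PooledSiteCount
    category: str
    x_allele: str | None
    y_allele: str | None
    freq_het: float  # chromosome-level alt frequency, heterogametic pool
    freq_hom: float


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": t.chrom, "pos": t.pos, "category": t.category,
                "x_allele": t.x_allele or "NA", "y_allele": t.y_allele or "NA",
                "freq_het": t.freq_het, "freq_hom": t.freq_hom,
            }
            for t in truth
        ],
        columns=["chrom", "pos", "category", "x_allele", "y_allele",
                 "freq_het", "freq_hom"],
    )


def _snap(freq: float, n_chrom: int) -> float:
    """Snap a population frequency to the k/n_chrom grid of a finite pool."""
    return round(freq * n_chrom) / n_chrom


def _sample_positions(rng: np.random.Generator, start: int, end: int, rate: float) -> np.ndarray:
    """0-based positions of events in [start, end) at a per-bp Bernoulli rate."""
    length = end - start
    n = rng.binomial(length, rate)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return start + np.sort(rng.choice(length, size=n, replace=False))


def _draw_counts(
    rng: np.random.Generator, mean_cov: float, freq: float, error: float
) -> tuple[int, int]:
    """(ref, alt) read counts at one site in one pool."""
    depth = int(rng.poisson(mean_cov))
    alt = int(rng.binomial(depth, freq)) if depth > 0 else 0
    ref = depth - alt
    if error > 0.0 and depth > 0:
        flip_to_ref = int(rng.binomial(alt, error))
        flip_to_alt = int(rng.binomial(ref, error))
        alt += flip_to_alt - flip_to_ref
        ref = depth - alt
    return ref, alt


def _alleles(rng: np.random.Generator, k: int = 2) -> list[str]:
    """k distinct bases, first one playing the reference/X role."""
    idx = rng.permutation(4)[:k]
    return [BASES[i] for i in idx]


def simulate_pools(config: SimConfig) -> tuple[list[PooledSiteCount], list[TruthRecord]]:
    """One species: pooled counts plus a truth table, deterministic under the seed.

    Pool1 is the heterogametic (male) pool.  At sex-patterned sites ref is
    the X allele and alt the Y allele, so the truth chromosome-level alt
    frequencies are 0.5 (males) and 0.0 (females).
    """
    rng = np.random.default_rng(config.seed)
    sd_chrom, sd_start, sd_end = config.sd_region
    n_het_chrom = 2 * config.n_males
    n_hom_chrom = 2 * config.n_females
    sites: list[PooledSiteCount] = []
    truth: list[TruthRecord] = []

    for chrom in config.chrom_lengths:
        length = config.chrom_lengths[chrom]
        bg_rate = config.background_snp_rate + config.monomorphic_rate
        bg_pos = _sample_positions(rng, 0, length, bg_rate)
        if config.monomorphic_rate > 0 and len(bg_pos):
            p_mono = config.monomorphic_rate / bg_rate
            mono_mask = rng.random(len(bg_pos)) < p_mono
        else:
            mono_mask = np.zeros(len(bg_pos), dtype=bool)
        if chrom == sd_chrom and config.sd_snp_rate > 0:
            sd_pos = _sample_positions(rng, sd_start, sd_end, config.sd_snp_rate)
        else:
            sd_pos = np.empty(0, dtype=np.int64)
        sd_set = set(int(p) for p in sd_pos)
        keep = np.array([int(p) not in sd_set for p in bg_pos], dtype=bool)
        bg_pos, mono_mask = bg_pos[keep], mono_mask[keep]

        events: list[tuple[int, str]] = [(int(p), CATEGORY_SEX) for p in sd_pos]
        events += [
            (int(p), CATEGORY_MONO if m else CATEGORY_BACKGROUND)
            for p, m in zip(bg_pos, mono_mask)
        ]
        events.sort()

        for pos0, category in events:
            ref, alt = _alleles(rng)
            pos = pos0 + 1
            if category == CATEGORY_SEX:
                f_het, f_hom = 0.5, 0.0
                x_al, y_al = ref, alt
            elif category == CATEGORY_BACKGROUND:
                f_pop = rng.integers(1, 10) / 10.0  # uniform on {0.1..0.9}
                f_het = _snap(f_pop, n_het_chrom)
                f_hom = _snap(f_pop, n_hom_chrom)
                x_al = y_al = None
            else:
                f_het = f_hom = 0.0
                x_al = y_al = None
            het = _draw_counts(rng, config.mean_coverage, f_het, config.seq_error_rate)
            hom = _draw_counts(rng, config.mean_coverage, f_hom, config.seq_error_rate)
            sites.append(PooledSiteCount(chrom, pos, ref, alt, *het, *hom))
            truth.append(TruthRecord(chrom, pos, category, x_al, y_al, f_het, f_hom))
    return sites, truth


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic apportionment of n items to len(fractions) classes."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts) if sum(fractions) >= 1.0 - 1e-12 else round(sum(raw)) - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class SharedTruthRecord:
    chrom: str
    pos: int
    fate: str  # CONSERVED | SWITCHED | SAME_X_DIFF_Y
    x_a: str
    y_a: str
    x_b: str
    y_b: str


def simulate_species_pair(
    config_a: SimConfig,
    config_b: SimConfig,
    shared_fraction: float,
    switch_fraction: float,
    y_replace_fraction: float,
    seed: int,
) -> tuple[
    tuple[list[PooledSiteCount], list[TruthRecord]],
    tuple[list[PooledSiteCount], list[TruthRecord]],
    list[SharedTruthRecord],
]:
    """Two species descending from one ancestral sex-determining region.

    Ancestral sex-patterned positions (drawn in the overlap of the two SD
    regions at config_a's sd_snp_rate) are partitioned by largest-remainder
    rounding into conserved / X-Y-switched / Y-replaced fates at the given
    fractions; the remainder is private to species A, and species B
    receives an equal number of private sites of its own.  Background and
    read sampling follow each species' own config.
    """
    fracs = (shared_fraction, switch_fraction, y_replace_fraction)
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("fate fractions must be non-negative and sum to <= 1")
    ca, sa, ea = config_a.sd_region
    cb, sb, eb = config_b.sd_region
    if ca != cb or max(sa, sb) >= min(ea, eb):
        raise ValueError("sd_regions of the two species must overlap")
    ov_start, ov_end = max(sa, sb), min(ea, eb)

    rng = np.random.default_rng(seed)
    anc_pos = _sample_positions(rng, ov_start, ov_end, config_a.sd_snp_rate)
    n_anc = len(anc_pos)
    n_cons, n_switch, n_yrep = _largest_remainder(n_anc, fracs)
    n_shared = n_cons + n_switch + n_yrep
    fates = (
        [SHARED_CONSERVED] * n_cons
        + [SHARED_SWITCHED] * n_switch
        + [SHARED_Y_REPLACED] * n_yrep
        + ["PRIVATE_A"] * (n_anc - n_shared)
    )
    rng.shuffle(fates)

    shared_truth: list[SharedTruthRecord] = []
    a_sex: list[tuple[int, str, str]] = []  # (pos0, X, Y)
    b_sex: list[tuple[int, str, str]] = []
    for pos0, fate in zip(anc_pos, fates):
        x_a, y_a, other = _alleles(rng, 3)
        a_sex.append((int(pos0), x_a, y_a))
        if fate == "PRIVATE_A":
            continue
        if fate == SHARED_CONSERVED:
            x_b, y_b = x_a, y_a
        elif fate == SHARED_SWITCHED:
            x_b, y_b = y_a, x_a
        else:  # Y replaced, X retained
            x_b, y_b = x_a, other
        b_sex.append((int(pos0), x_b, y_b))
        shared_truth.append(
            SharedTruthRecord(ca, int(pos0) + 1, fate, x_a, y_a, x_b, y_b)
        )

    # private sites for B, avoiding all ancestral positions
    anc_set = set(int(p) for p in anc_pos)
    n_priv_b = n_anc - n_shared
    while True:
        cand = rng.choice(eb - sb, size=min(eb - sb, 2 * n_priv_b + 8), replace=False) + sb
        cand = [int(p) for p in cand if int(p) not in anc_set][:n_priv_b]
        if len(cand) == n_priv_b:
            break
    for pos0 in sorted(cand):
        x_b, y_b = _alleles(rng)
        b_sex.append((pos0, x_b, y_b))
    b_sex.sort()

    dataset_a = _assemble_species(config_a, a_sex, rng.integers(2**31))
    dataset_b = _assemble_species(config_b, b_sex, rng.integers(2**31))
    return dataset_a, dataset_b, shared_truth


def _assemble_species(
    config: SimConfig, sex_sites: list[tuple[int, str, str]], seed: int
) -> tuple[list[PooledSiteCount], list[TruthRecord]]:
    """Background via simulate_pools (sd rate zeroed) plus explicit sex sites."""
    bg_cfg = replace(config, sd_snp_rate=0.0, seed=int(seed))
    sites, truth = simulate_pools(bg_cfg)
    rng = np.random.default_rng(int(seed) + 1)
    sd_chrom = config.sd_region[0]
    sex_positions = {pos0 + 1 for pos0, _, _ in sex_sites}
    keep = [
        (s, t)
        for s, t in zip(sites, truth)
        if not (s.chrom == sd_chrom and s.pos in sex_positions)
    ]
    sites = [s for s, _ in keep]
    truth = [t for _, t in keep]
    for pos0, x_al, y_al in sex_sites:
        het = _draw_counts(rng, config.mean_coverage, 0.5, config.seq_error_rate)
        hom = _draw_counts(rng, config.mean_coverage, 0.0, config.seq_error_rate)
        sites.append(PooledSiteCount(sd_chrom, pos0 + 1, x_al, y_al, *het, *hom))
        truth.append(
            TruthRecord(sd_chrom, pos0 + 1, CATEGORY_SEX, x_al, y_al, 0.5, 0.0)
        )
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    return [sites[i] for i in order], [truth[i] for i in order]


# ---------------------------------------------------------------------------
# CNV tracks


def simulate_cnv_tracks(
    n_comparisons: int,
    true_cnvs: Sequence[tuple[tuple[str, int, int], str]],
    noise_rate: float,
    seed: int,
    jitter: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    mean_depth: float = 35.0,
) -> tuple[list[list[VarScanSegment]], list[tuple[tuple[str, int, int], str]]]:
    """n VarScan-style tracks in which every true CNV is conserved.

    true_cnvs are ((chrom, start, end), "AMP"|"DEL") with 0-based half-open
    intervals.  Each true CNV appears in every track, tiled into segments
    of 100 bp-1 kb with |log2 ratio| in [0.2, 1.5] and the direction's
    sign; boundaries are jittered by at most ``jitter`` bp.  noise_rate is
    the expected number of single-track noise segments per track, placed
    without overlapping any true CNV or other noise segment.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if jitter < 0 or noise_rate < 0:
        raise ValueError("jitter and noise_rate must be non-negative")
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {}
        for (chrom, _s, e), _d in true_cnvs:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), 2 * e)
        if not chrom_lengths:
            chrom_lengths = {"LG1": 1_000_000}

    occupied: list[tuple[str, int, int]] = [
        (c, max(0, s - jitter), e + jitter) for (c, s, e), _ in true_cnvs
    ]

    def _overlaps(chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and start < oe and os_ < end for c, os_, oe in occupied)

    tracks: list[list[VarScanSegment]] = []
    for _track in range(n_comparisons):
        segs: list[VarScanSegment] = []
        for (chrom, start, end), direction in true_cnvs:
            sign = 1.0 if direction == "AMP" else -1.0
            s = start if jitter == 0 else max(0, start - int(rng.integers(0, jitter + 1)))
            e = end if jitter == 0 else end + int(rng.integers(0, jitter + 1))
            segs.extend(_tile_segment(rng, chrom, s, e, sign, mean_depth))
        n_noise = int(rng.poisson(noise_rate))
        for _ in range(n_noise):
            for _attempt in range(200):
                chrom = list(chrom_lengths)[int(rng.integers(len(chrom_lengths)))]
                width = int(rng.integers(100, 1001))
                start = int(rng.integers(0, max(1, chrom_lengths[chrom] - width)))
                if not _overlaps(chrom, start, start + width):
                    break
            else:
                continue
            occupied.append((chrom, start, start + width))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            segs.extend(_tile_segment(rng, chrom, start, start + width, sign, mean_depth))
        segs.sort(key=lambda s: (s.chrom, s.start, s.end))
        tracks.append(segs)
    return tracks, list(true_cnvs)


def _tile_segment(
    rng: np.random.Generator, chrom: str, start: int, end: int,
    sign: float, mean_depth: float,
) -> list[VarScanSegment]:
    """Tile [start, end) into VarScan-style rows of 100 bp-1 kb."""
    out: list[VarScanSegment] = []
    bounds = list(range(start, end, 1000)) + [end]
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < 100:
        bounds.pop(-2)  # fold a short trailing chunk into its neighbour
    for s, e in zip(bounds, bounds[1:]):
        log2 = sign * float(rng.uniform(0.2, 1.5))
        d1 = mean_depth
        d2 = mean_depth * 2.0**log2
        out.append(
            VarScanSegment(
                chrom=chrom, start=s + 1, end=e, n_positions=e - s,
                depth1=round(d1, 2), depth2=round(d2, 2),
                log2_ratio=round(log2, 4),
            )
        )
    return out
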