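import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolsex import windows as win
from poolsex.io_formats import GapInterval
from poolsex.windows import Region, WindowSummary
from conftest import make_stats


def make_windows(counts, chrom="LG1", size=10_000):
    return [
        WindowSummary(chrom, i * size, (i + 1) * size, c, c, size)
        for i, c in enumerate(counts)
    ]


class TestWindowCounts:
    def test_boundary_convention(self):
        stats = [make_stats(pos=10_000, sex_patterned=True),
                 make_stats(pos=10_001, sex_patterned=True)]
        wins = win.window_counts(stats, 10_000, chrom_lengths={"LG1": 20_000})
        assert [w.n_sex_patterned for w in wins] == [1, 1]
        assert (wins[0].start, wins[0].end) == (0, 10_000)
        assert (wins[1].start, wins[1].end) == (10_000, 20_000)

    def test_no_sites_gives_all_zero_windows(self):
        wins = win.window_counts([], 10_000, chrom_lengths={"LG1": 35_000})
        assert len(wins) == 4  # trailing partial window kept
        assert wins[-1].end == 35_000
        assert all(w.n_total_snps == 0 for w in wins)

    def test_counts_conserve_total(self, rng):
        positions = sorted(rng.choice(100_000, size=25, replace=False) + 1)
        stats = [make_stats(pos=int(p), sex_patterned=True) for p in positions]
        wins = win.window_counts(stats, 10_000, chrom_lengths={"LG1": 100_000})
        assert sum(w.n_sex_patterned for w in wins) == 25
        # brute-force recount per window
        for w in wins:
            assert w.n_sex_patterned == sum(
                1 for p in positions if w.start < p <= w.end
            )

    def test_gap_overlap_reduces_effective_length(self):
        gaps = [GapInterval("LG1", 2_000, 6_000), GapInterval("LG1", 9_000, 12_000)]
        wins = win.window_counts([], 10_000, gaps, {"LG1": 20_000})
        assert wins[0].effective_len == 10_000 - 4_000 - 1_000
        assert wins[1].effective_len == 10_000 - 2_000

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ValueError):
            win.window_counts([], 0)


class TestEnrichment:
    def test_at_least_ten_is_inclusive(self):
        wins = make_windows([10, 9, 11])
        win.call_enriched(wins)
        assert [w.enriched for w in wins] == [True, False, True]

    def test_raising_threshold_never_adds_windows(self, rng):
        wins = make_windows(list(rng.integers(0, 30, size=40)))
        n_prev = None
        for min_snps in (5, 10, 15, 20):
            n = sum(w.enriched for w in win.call_enriched(wins, min_snps))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestRegionSummary:
    # printed Table-1-style densities recomputed from counts and region lengths
    @pytest.mark.parametrize(
        "count, length, density",
        [
            (5342, 8_800_000, 607.05),
            (10792, 8_800_000, 1226.36),
            (2702, 9_100_000, 296.92),
            (399, 1_900_000, 210.00),
            (193, 8_800_000, 21.93),
            (517, 8_800_000, 58.75),
            (61, 8_800_000, 6.93),
            (121, 8_800_000, 13.75),
        ],
    )
    def test_densities_reproduce_published_rounding(self, count, length, density):
        assert win.density_per_mb(count, length) == density

    def test_zero_sites_region(self):
        region = Region("r", (("LG1", 0, 10_000),))
        summary = win.summarize_region([], [], region)
        assert summary.n_sex_patterned == 0
        assert summary.density_per_mb == 0.0
        assert summary.mean_fst_polymorphic is None

    def test_mean_fst_uses_all_polymorphic_sites(self):
        region = Region("r", (("LG1", 0, 1_000_000),))
        stats = [
            make_stats(pos=10, sex_patterned=True, fst=0.8),
            make_stats(pos=20, sex_patterned=False, fst=0.2),
            make_stats(pos=30, sex_patterned=False, fst=None),  # monomorphic: excluded
        ]
        summary = win.summarize_region(stats, [], region)
        assert summary.mean_fst_polymorphic == pytest.approx(0.5)
        assert summary.n_sex_patterned == 1

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            Region("r", (("LG1", 5, 5),))

    def test_complement_covers_rest_of_genome(self):
        named = Region("sd", (("LG1", 100, 200),))
        rest = Region.complement({"LG1": 1000, "LG2": 500}, [named])
        assert rest.intervals == (("LG1", 0, 100), ("LG1", 200, 1000), ("LG2", 0, 500))
        assert rest.length_bp + named.length_bp == 1500


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = win.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        u, p = win.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n_a*n_b/2
        assert p > 0.9

    def test_exact_and_approximate_agree(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, p_exact = win.mann_whitney_u(a, b)  # 16 values, no ties: exact
            from scipy.stats import mannwhitneyu

            p_approx = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.02

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=12),
           st.lists(st.integers(0, 50), min_size=3, max_size=12),
           st.integers(-5, 5))
    @settings(derandomize=True, max_examples=40)
    def test_symmetry_and_shift_invariance(self, a, b, shift):
        _, p_ab = win.mann_whitney_u(a, b)
        _, p_ba = win.mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)
        _, p_shift = win.mann_whitney_u([x + shift for x in a], [x + shift for x in b])
        assert p_shift == pytest.approx(p_ab)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            win.mann_whitney_u([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.05, 12, 0.004167), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_threshold(self, alpha, m, expected):
        assert win.bonferroni_alpha(alpha, m) == expected

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            win.bonferroni_alpha(0.05, 0)


class TestCompareRegions:
    def _regions(self):
        enriched = Region("sd", (("LG1", 0, 300_000),))
        rest = Region("rest", (("LG1", 300_000, 1_000_000),))
        return enriched, rest

    def test_empty_pair_list_gives_empty_table(self):
        assert win.compare_regions(make_windows([1, 2]), []).empty

    def test_overlapping_pair_rejected(self):
        a = Region("a", (("LG1", 0, 200_000),))
        b = Region("b", (("LG1", 100_000, 300_000),))
        with pytest.raises(ValueError, match="overlap"):
            win.compare_regions(make_windows([1, 2]), [(a, b)])

    def test_enriched_region_detected(self, rng):
        enriched, rest = self._regions()
        counts = list(rng.poisson(20, size=30)) + list(rng.poisson(1, size=70))
        table = win.compare_regions(make_windows(counts), [(enriched, rest)])
        row = table.iloc[0]
        assert row["significant"]
        assert row["p"] < 1e-4
        assert row["n_windows_a"] == 30 and row["n_windows_b"] == 70

    def test_null_halves_not_significant(self):
        # same Poisson law in both halves: type-I control at alpha/12 over 3 seeds
        enriched, rest = self._regions()
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            counts = list(rng.poisson(5, size=100))
            table = win.compare_regions(make_windows(counts), [(enriched, rest)])
            assert not table.iloc[0]["significant"]
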