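import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolsex import sexsnp
from poolsex.sexsnp import DetectorParams
from conftest import make_site

counts = st.integers(min_value=0, max_value=200)


class TestClassify:
    @pytest.mark.parametrize(
        "p1r, p1a, p2r, p2a, evaluated, sex",
        [
            (18, 12, 30, 0, True, True),    # male p=0.4, female fixed ref
            (5, 4, 30, 0, False, False),    # male depth 9 < 10
            (29, 1, 30, 0, True, False),    # freq 0.033 and count 1 both fail
            (21, 9, 30, 0, True, True),     # het freq exactly 0.3: inclusive
            (9, 21, 30, 0, True, True),     # het freq exactly 0.7: inclusive
            (8, 22, 30, 0, True, False),    # 0.733 above the band
            (15, 15, 27, 3, True, True),    # female minor 0.1: still nearly fixed
            (15, 15, 26, 4, True, False),   # female minor 0.133: not fixed
        ],
    )
    def test_threshold_behaviour(self, p1r, p1a, p2r, p2a, evaluated, sex):
        stats = sexsnp.classify_site(make_site(p1_ref=p1r, p1_alt=p1a,
                                               p2_ref=p2r, p2_alt=p2a))
        assert stats.evaluated is evaluated
        assert stats.is_sex_patterned is sex

    def test_y_allele_identified(self):
        stats = sexsnp.classify_site(make_site(p1_ref=18, p1_alt=12, p2_ref=30, p2_alt=0))
        assert (stats.x_allele, stats.y_allele) == ("A", "G")

    def test_near_fixed_on_alt_swaps_alleles(self):
        stats = sexsnp.classify_site(make_site(p1_ref=14, p1_alt=16, p2_ref=1, p2_alt=29))
        assert stats.is_sex_patterned
        assert (stats.x_allele, stats.y_allele) == ("G", "A")

    def test_wz_system_via_pool_swap(self):
        params = DetectorParams(heterogametic_pool=2)
        stats = sexsnp.classify_site(
            make_site(p1_ref=30, p1_alt=0, p2_ref=18, p2_alt=12), params
        )
        assert stats.is_sex_patterned

    def test_min_allele_count_guards_candidate_allele(self):
        params = DetectorParams(het_low=0.0001, homog_fixed_max=0.0, min_allele_count=2)
        site = make_site(p1_ref=999, p1_alt=1, p2_ref=30, p2_alt=0)
        assert not sexsnp.classify_site(site, params).is_sex_patterned


class TestCp:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 0), (0, 1), 1.0),
            ((0.3, 0.7), (0.3, 0.7), 0.0),
            ((0.5, 0.5), (1, 0), 0.5),
        ],
    )
    def test_examples(self, x, y, expected):
        assert sexsnp.compute_cp(x, y) == pytest.approx(expected)

    def test_mismatched_allele_sets_rejected(self):
        with pytest.raises(ValueError):
            sexsnp.compute_cp([1, 0], [0.5, 0.25, 0.25])

    @given(px=st.floats(0, 1), py=st.floats(0, 1))
    @settings(derandomize=True, max_examples=60)
    def test_biallelic_cp_equals_frequency_difference(self, px, py):
        cp = sexsnp.compute_cp([1 - px, px], [1 - py, py])
        assert cp == pytest.approx(abs(px - py))


class TestFst:
    def test_identical_pools_give_zero(self):
        site = make_site(p1_ref=13, p1_alt=7, p2_ref=13, p2_alt=7)
        assert sexsnp.compute_fst(site) == pytest.approx(0.0)

    def test_monomorphic_site_is_undefined(self):
        assert sexsnp.compute_fst(make_site(p1_ref=20, p1_alt=0, p2_ref=40, p2_alt=0)) is None

    def test_low_depth_is_undefined(self):
        assert sexsnp.compute_fst(make_site(p1_ref=1, p1_alt=0, p2_ref=40, p2_alt=0)) is None

    def test_worked_example(self):
        # pi1=(40/39)*0.5, pi2=0, piT=(80/79)*0.375 -> 0.3248
        site = make_site(p1_ref=20, p1_alt=20, p2_ref=40, p2_alt=0)
        assert sexsnp.compute_fst(site) == pytest.approx(0.324786, abs=1e-6)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_pool_swap(self, a, b, c, d):
        s1 = make_site(p1_ref=a, p1_alt=b, p2_ref=c, p2_alt=d)
        s2 = make_site(p1_ref=c, p1_alt=d, p2_ref=a, p2_alt=b)
        f1, f2 = sexsnp.compute_fst(s1), sexsnp.compute_fst(s2)
        if f1 is None or f2 is None:
            assert f1 is None and f2 is None
        else:
            assert f1 == pytest.approx(f2)


class TestDxyDaNei:
    @pytest.mark.parametrize(
        "p1r, p1a, p2r, p2a, dxy",
        [
            (40, 0, 0, 40, 1.0),    # fixed difference
            (40, 0, 40, 0, 0.0),
        ],
    )
    def test_dxy_fixed_cases(self, p1r, p1a, p2r, p2a, dxy):
        got_dxy, got_da = sexsnp.compute_dxy_da(
            make_site(p1_ref=p1r, p1_alt=p1a, p2_ref=p2r, p2_alt=p2a)
        )
        assert got_dxy == pytest.approx(dxy)
        assert got_da == pytest.approx(dxy)  # both pools monomorphic

    def test_dxy_da_worked_example(self):
        site = make_site(p1_ref=20, p1_alt=20, p2_ref=40, p2_alt=0)
        dxy, da = sexsnp.compute_dxy_da(site)
        assert dxy == pytest.approx(0.5)
        assert da == pytest.approx(0.5 - (40 / 39) * 0.5 / 2)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=100)
    def test_da_never_exceeds_dxy(self, a, b, c, d):
        if a + b < 2 or c + d < 2:
            return
        dxy, da = sexsnp.compute_dxy_da(make_site(p1_ref=a, p1_alt=b, p2_ref=c, p2_alt=d))
        assert da <= dxy + 1e-12

    def test_nei_d_identical_frequencies_is_zero(self):
        assert sexsnp.compute_nei_d(
            make_site(p1_ref=15, p1_alt=15, p2_ref=20, p2_alt=20)
        ) == pytest.approx(0.0)

    def test_nei_d_alternatively_fixed_uses_max_coverage_clamp(self):
        site = make_site(p1_ref=40, p1_alt=0, p2_ref=0, p2_alt=40)
        d = sexsnp.compute_nei_d(site, DetectorParams(max_coverage=100))
        x = np.array([0.99, 0.01])
        expected = -math.log((x[0] * x[1] * 2) / (x @ x))
        assert d == pytest.approx(expected)
        assert d == pytest.approx(3.902, abs=0.001)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=100)
    def test_nei_d_non_negative(self, a, b, c, d):
        if a + b < 1 or c + d < 1:
            return
        assert sexsnp.compute_nei_d(make_site(p1_ref=a, p1_alt=b, p2_ref=c, p2_alt=d)) >= 0.0


class TestScanDataset:
    def test_empty_input_gives_empty_output(self):
        assert sexsnp.scan_dataset([]) == []

    def test_one_stats_per_site(self):
        sites = [make_site(pos=p) for p in (10, 20, 30)]
        assert len(sexsnp.scan_dataset(sites)) == 3

    def test_unsorted_input_is_hard_error(self):
        with pytest.raises(ValueError, match="sorted"):
            sexsnp.scan_dataset([make_site(pos=20), make_site(pos=10)])
        with pytest.raises(ValueError, match="sorted"):
            sexsnp.scan_dataset(
                [make_site(chrom="c1"), make_site(chrom="c2"), make_site(chrom="c1", pos=200)]
            )

    def test_undefined_statistics_written_as_na(self, tmp_path):
        sites = [
            make_site(pos=10, p1_ref=20, p1_alt=0, p2_ref=20, p2_alt=0),  # fst undefined
            make_site(pos=20, p1_ref=3, p1_alt=2, p2_ref=3, p2_alt=2),    # below min depth
        ]
        stats = sexsnp.scan_dataset(sites)
        path = tmp_path / "stats.tsv"
        sexsnp.write_sitestats(stats, path)
        frame = sexsnp.read_sitestats(path)
        assert frame["fst"].isna().all()
        assert list(frame["evaluated"]) == [1, 0]
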