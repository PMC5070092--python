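from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from poolsex import sexsnp, simulate
from poolsex.simulate import SimConfig


def small_config(**kw):
    defaults = dict(
        chrom_lengths={"LG1": 200_000},
        sd_region=("LG1", 50_000, 150_000),
        sd_snp_rate=0.002,
        background_snp_rate=0.001,
        mean_coverage=35.0,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulatePools:
    def test_same_seed_gives_identical_output(self, tmp_path):
        from poolsex.io_formats import write_sync_table

        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for p in (p1, p2):
            sites, _ = simulate.simulate_pools(small_config())
            write_sync_table(sites, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_rates_give_zero_sites(self):
        sites, truth = simulate.simulate_pools(
            small_config(sd_snp_rate=0.0, background_snp_rate=0.0)
        )
        assert sites == [] and truth == []

    def test_empty_sd_region_with_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            small_config(sd_region=("LG1", 50_000, 50_000), sd_snp_rate=0.01)

    def test_male_pool_alt_fraction_centers_on_half(self):
        # ~10,000 sex-patterned sites at coverage 1000: SE of the mean alt
        # fraction is ~ sqrt(0.25/1000)/sqrt(10000) ~ 1.6e-4, far inside 0.01
        cfg = small_config(
            chrom_lengths={"LG1": 1_000_000},
            sd_region=("LG1", 0, 1_000_000),
            sd_snp_rate=0.01,
            background_snp_rate=0.0,
            mean_coverage=1000.0,
            seed=3,
        )
        sites, truth = simulate.simulate_pools(cfg)
        assert len(sites) > 9000
        fracs = np.array([s.pool1_alt / s.pool1_depth for s in sites])
        assert abs(fracs.mean() - 0.5) < 0.01
        assert all(s.pool2_alt == 0 for s in sites)

    def test_truth_frequencies_lie_on_chromosome_count_grid(self):
        cfg = small_config(seed=5)
        _, truth = simulate.simulate_pools(cfg)
        n_het, n_hom = 2 * cfg.n_males, 2 * cfg.n_females
        for t in truth:
            assert Fraction(t.freq_het).limit_denominator(n_het) * n_het % 1 == 0
            assert Fraction(t.freq_hom).limit_denominator(n_hom) * n_hom % 1 == 0

    def test_sites_sorted_and_positions_unique(self):
        sites, truth = simulate.simulate_pools(small_config(seed=9))
        sexsnp.check_sorted(sites)  # raises on violation
        assert len({(s.chrom, s.pos) for s in sites}) == len(sites)
        assert len(truth) == len(sites)

    def test_detector_recall_rises_with_coverage(self):
        recalls = []
        for cov in (10.0, 35.0, 100.0):
            cfg = small_config(
                chrom_lengths={"LG1": 1_000_000},
                sd_region=("LG1", 0, 1_000_000),
                sd_snp_rate=0.002,  # ~2,000 sex-patterned sites
                background_snp_rate=0.0,
                mean_coverage=cov,
                seed=17,
            )
            sites, truth = simulate.simulate_pools(cfg)
            stats = sexsnp.scan_dataset(sites, sexsnp.DetectorParams())
            truth_pos = {t.pos for t in truth}
            hit = sum(1 for s in stats if s.is_sex_patterned and s.pos in truth_pos)
            recalls.append(hit / len(truth_pos))
        assert recalls[0] <= recalls[1] + 0.02 <= recalls[2] + 0.04


class TestSpeciesPair:
    def test_zero_fractions_give_empty_intersection(self):
        cfg = small_config()
        (_, ta), (_, tb), shared_truth = simulate.simulate_species_pair(
            cfg, cfg, 0.0, 0.0, 0.0, seed=2
        )
        assert shared_truth == []
        pos_a = {t.pos for t in ta if t.category == simulate.CATEGORY_SEX}
        pos_b = {t.pos for t in tb if t.category == simulate.CATEGORY_SEX}
        assert pos_a.isdisjoint(pos_b)

    def test_fate_allocation_is_deterministic_rounding(self):
        assert simulate._largest_remainder(100, (0.5, 0.25, 0.25)) == [50, 25, 25]
        assert simulate._largest_remainder(10, (0.34, 0.33, 0.33)) == [4, 3, 3]
        assert sum(simulate._largest_remainder(7, (0.5, 0.2, 0.1))) == round(7 * 0.8)

    def test_fate_classes_match_requested_fractions(self):
        cfg = small_config(sd_snp_rate=0.005, seed=21)
        _, _, shared_truth = simulate.simulate_species_pair(
            cfg, cfg, 0.5, 0.25, 0.25, seed=21
        )
        n = len(shared_truth)
        got = Counter(t.fate for t in shared_truth)
        want = simulate._largest_remainder(n, (0.5, 0.25, 0.25))
        assert [got[simulate.SHARED_CONSERVED], got[simulate.SHARED_SWITCHED],
                got[simulate.SHARED_Y_REPLACED]] == want

    def test_disjoint_sd_regions_rejected(self):
        a = small_config(sd_region=("LG1", 0, 10_000))
        b = small_config(sd_region=("LG1", 20_000, 30_000))
        with pytest.raises(ValueError, match="overlap"):
            simulate.simulate_species_pair(a, b, 0.5, 0.2, 0.2, seed=1)


class TestCnvTracks:
    TRUE = [(("LG1", 10_000, 12_500), "AMP"), (("LG1", 50_000, 50_400), "DEL")]

    def test_noiseless_tracks_tile_truth_exactly(self):
        tracks, truth = simulate.simulate_cnv_tracks(
            3, self.TRUE, noise_rate=0.0, seed=4, jitter=0
        )
        assert truth == self.TRUE
        for track in tracks:
            covered = {}
            for seg in track:
                s, e = seg.interval
                covered.setdefault(seg.chrom, []).append((s, e, seg.log2_ratio))
            spans = sorted((s, e) for s, e, _ in covered["LG1"])
            # segments tile exactly the two true intervals, 100 bp - 1 kb each
            assert spans[0][0] == 10_000 and spans[-1][1] == 50_400
            for s, e in spans:
                assert 100 <= e - s <= 1000
            for s, e, log2 in covered["LG1"]:
                direction = "AMP" if log2 > 0 else "DEL"
                inside = [d for (c, ts, te), d in self.TRUE if ts <= s and e <= te]
                assert inside == [direction]
                assert abs(log2) >= 0.2

    def test_fixed_seed_reproducible(self):
        t1, _ = simulate.simulate_cnv_tracks(2, self.TRUE, 1.0, seed=8)
        t2, _ = simulate.simulate_cnv_tracks(2, self.TRUE, 1.0, seed=8)
        assert t1 == t2

    def test_noise_segments_are_private_to_one_track(self):
        tracks, _ = simulate.simulate_cnv_tracks(
            3, self.TRUE, noise_rate=5.0, seed=12,
            chrom_lengths={"LG1": 500_000},
        )
        true_spans = [(s, e) for (c, s, e), _ in self.TRUE]

        def is_noise(seg):
            s, e = seg.interval
            return not any(ts <= s and e <= te for ts, te in true_spans)

        noise = [
            (i, seg.interval) for i, track in enumerate(tracks)
            for seg in track if is_noise(seg)
        ]
        for i, (s, e) in noise:
            for j, (s2, e2) in noise:
                if i != j:
                    assert e <= s2 or e2 <= s  # no cross-track overlap
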