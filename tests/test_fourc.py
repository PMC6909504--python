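"""4C quantification: smoothing, window normalization, distributions, G test."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from allelichrom import simulate
from allelichrom.fourc import (
    FragmentTrack,
    NormalizationWindow,
    allelic_subdomain_test,
    g_test_2x2,
    normalize_to_window,
    ratio_track,
    smooth_track,
    subdomain_distribution,
)
from allelichrom.genome import GenomicInterval, SubdomainPartition


def make_track(fmap, values, viewpoint_frag=5, allele="combined"):
    vp = fmap.fragment(viewpoint_frag)
    return FragmentTrack(fmap, np.asarray(values, dtype=float), vp, allele=allele)


class TestSmooth:
    def test_constant_track_stays_constant(self, small_fragment_map):
        t = make_track(small_fragment_map, [7.0] * 14)
        assert np.allclose(smooth_track(t, 5).values, 7.0)

    def test_window_one_is_identity(self, small_fragment_map, rng):
        values = rng.random(14)
        t = make_track(small_fragment_map, values)
        assert np.allclose(smooth_track(t, 1).values, values)

    def test_matches_truncated_window_mean_oracle(self, rng):
        fmap = simulate.simulate_fragment_map(100_000, seed=3, chrom="c")
        values = rng.random(fmap.n_fragments) * 100
        out = smooth_track(make_track(fmap, values), 11).values
        half = 5
        for i in range(values.size):
            lo, hi = max(0, i - half), min(values.size, i + half + 1)
            assert out[i] == pytest.approx(values[lo:hi].mean())

    def test_monotone_in_argument(self, small_fragment_map, rng):
        a = rng.random(14)
        b = a + rng.random(14)  # everywhere >= a
        sa = smooth_track(make_track(small_fragment_map, a), 5).values
        sb = smooth_track(make_track(small_fragment_map, b), 5).values
        assert (sb >= sa - 1e-12).all()

    def test_window_validation(self, small_fragment_map):
        t = make_track(small_fragment_map, np.ones(14))
        with pytest.raises(ValueError):
            smooth_track(t, 4)  # even
        with pytest.raises(ValueError):
            smooth_track(t, 15)  # longer than track


class TestNormalizeToWindow:
    def test_scale_factor(self, small_fragment_map):
        # all signal well away from the viewpoint mask
        values = np.zeros(14)
        values[10:14] = [2000, 1000, 1500, 500]  # in-window sum 5000
        t = make_track(small_fragment_map, values, viewpoint_frag=2)
        window = NormalizationWindow(GenomicInterval("chrT", 0, 10_000), 1e6)
        out = normalize_to_window(t, window)
        assert np.allclose(out.values[10:14] / values[10:14], 200.0)

    def test_in_window_total_hits_target_and_is_idempotent(self, rng):
        fmap = simulate.simulate_fragment_map(200_000, seed=4, chrom="c")
        values = rng.random(fmap.n_fragments) * 50
        t = make_track(fmap, values, viewpoint_frag=40)
        window = NormalizationWindow(GenomicInterval("c", 0, 200_000), 1e6)
        out = normalize_to_window(t, window)
        usable = ~out.viewpoint_mask()
        assert out.values[usable].sum() == pytest.approx(1e6)
        again = normalize_to_window(out, window)
        assert np.allclose(again.values, out.values)

    def test_zero_window_signal_rejected(self, small_fragment_map):
        t = make_track(small_fragment_map, np.zeros(14))
        with pytest.raises(ValueError):
            normalize_to_window(t, NormalizationWindow(GenomicInterval("chrT", 0, 10_000)))


class TestRatioTrack:
    def test_equal_tracks_give_zero(self, small_fragment_map):
        m = make_track(small_fragment_map, np.full(14, 8.0), allele="maternal")
        p = make_track(small_fragment_map, np.full(14, 8.0), allele="paternal")
        assert np.allclose(ratio_track(m, p), 0.0)

    def test_twofold_is_one(self, small_fragment_map):
        m = make_track(small_fragment_map, np.full(14, 8.0))
        p = make_track(small_fragment_map, np.full(14, 4.0))
        assert np.allclose(ratio_track(m, p), 1.0)

    def test_pseudocount_arithmetic(self, small_fragment_map):
        m = make_track(small_fragment_map, np.full(14, 3.0))
        p = make_track(small_fragment_map, np.full(14, 1.0))
        assert np.allclose(ratio_track(m, p, pseudocount=1.0), math.log2(4 / 2))


class TestSubdomainDistribution:
    def partition(self):
        dom = GenomicInterval("c", 0, 100_000)
        return SubdomainPartition(
            dom,
            (
                ("left", GenomicInterval("c", 0, 50_000)),
                ("right", GenomicInterval("c", 50_000, 100_000)),
            ),
        )

    def test_uniform_per_bp_signal_gives_equal_shares(self):
        fmap = simulate.simulate_fragment_map(100_000, seed=9, chrom="c")
        values = np.diff(fmap.boundaries).astype(float)  # signal ~ fragment length
        t = make_track(fmap, values, viewpoint_frag=fmap.n_fragments - 1)
        sig = subdomain_distribution(t, self.partition())
        assert sig.shares[0] == pytest.approx(0.5, abs=0.02)
        assert sig.per_part_density[0] == pytest.approx(sig.per_part_density[1], rel=0.05)

    def test_all_signal_in_one_part(self):
        fmap = simulate.simulate_fragment_map(100_000, seed=9, chrom="c")
        values = np.zeros(fmap.n_fragments)
        values[1] = 100.0  # early fragment, inside "left"
        t = make_track(fmap, values, viewpoint_frag=fmap.n_fragments - 1)
        sig = subdomain_distribution(t, self.partition())
        assert sig.shares.tolist() == [1.0, 0.0]

    def test_matches_per_fragment_assignment_oracle(self, rng):
        fmap = simulate.simulate_fragment_map(100_000, seed=10, chrom="c")
        values = rng.random(fmap.n_fragments) * 10
        t = make_track(fmap, values, viewpoint_frag=3)
        part = self.partition()
        sig = subdomain_distribution(t, part)
        # oracle: direct midpoint assignment, skipping the viewpoint mask
        mask = t.viewpoint_mask()
        expected = [0.0, 0.0]
        for i in range(fmap.n_fragments):
            if mask[i]:
                continue
            mid = (fmap.boundaries[i] + fmap.boundaries[i + 1]) / 2
            expected[0 if mid < 50_000 else 1] += values[i]
        assert np.allclose(sig.per_part_signal, expected)
        assert np.allclose(
            sig.per_part_density, np.array(expected) / 0.05
        )  # 50 kb = 0.05 Mb


class TestGTest:
    def test_independent_table_gives_zero(self):
        result = g_test_2x2([[10, 10], [10, 10]])
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_diagonal_closed_form(self):
        result = g_test_2x2([[5, 0], [0, 5]])
        assert result.statistic == pytest.approx(20 * math.log(2), rel=1e-12)
        assert result.p_value == pytest.approx(
            1.9663765560e-4, rel=1e-6
        )  # chi2(1) tail at 20 ln 2

    def test_proportional_rows_give_zero(self):
        assert g_test_2x2([[3, 9], [5, 15]]).statistic == pytest.approx(0.0, abs=1e-12)

    def test_mutual_information_identity(self, rng):
        # G = 2 * n * I(rows; cols) in nats
        for _ in range(100):
            table = rng.integers(1, 60, size=(2, 2)).astype(float)
            n = table.sum()
            p = table / n
            pr, pc = p.sum(axis=1), p.sum(axis=0)
            mi = sum(
                p[i, j] * math.log(p[i, j] / (pr[i] * pc[j]))
                for i in range(2)
                for j in range(2)
                if p[i, j] > 0
            )
            assert g_test_2x2(table).statistic == pytest.approx(2 * n * mi, abs=1e-9)

    def test_matches_scipy_log_likelihood_ratio(self, rng):
        for _ in range(50):
            table = rng.integers(1, 80, size=(2, 2))
            result = g_test_2x2(table)
            g, p, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert result.statistic == pytest.approx(g, rel=1e-10)
            assert result.p_value == pytest.approx(p, rel=1e-8)

    def test_swap_invariance(self, rng):
        table = rng.integers(1, 40, size=(2, 2))
        g = g_test_2x2(table).statistic
        assert g_test_2x2(table[::-1]).statistic == pytest.approx(g)
        assert g_test_2x2(table[:, ::-1]).statistic == pytest.approx(g)
        assert g_test_2x2(table.T).statistic == pytest.approx(g)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            g_test_2x2([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            g_test_2x2([[5, 0], [5, 0]])


class TestAllelicSubdomainTest:
    def setup_tracks(self, seed, planted):
        spec = simulate.default_domain_spec()
        vp_bin = 132
        boosts = {"maternal": {"subtad": 2.0}} if planted else None
        mats = simulate.simulate_contact_matrix(
            spec, subtad_boost_by_allele=boosts, noise_dispersion=None
        )
        rng = np.random.default_rng(seed)
        fmap = simulate.simulate_fragment_map(spec.chrom_length, seed=rng)
        window = NormalizationWindow(GenomicInterval(spec.chrom, 0, spec.chrom_length))
        tracks = {}
        for allele in ("maternal", "paternal"):
            t = simulate.simulate_4c_counts(
                mats[allele], vp_bin, 100_000, fmap, seed=rng, allele=allele
            )
            tracks[allele] = normalize_to_window(t, window)
        return spec, tracks

    def test_planted_enrichment_detected(self):
        for seed in range(5):
            spec, tracks = self.setup_tracks(seed, planted=True)
            result = allelic_subdomain_test(
                tracks["maternal"],
                tracks["paternal"],
                spec.partition.interval("subtad"),
                spec.partition.interval("telomeric"),
            )
            assert result.p_value < 0.01
            assert result.row_fractions[0] > result.row_fractions[1]

    def test_null_is_not_rejected_wholesale(self):
        pvals = [
            allelic_subdomain_test(
                tracks["maternal"],
                tracks["paternal"],
                spec.partition.interval("subtad"),
                spec.partition.interval("telomeric"),
            ).p_value
            for seed in range(10)
            for spec, tracks in [self.setup_tracks(100 + seed, planted=False)]
        ]
        assert sum(p < 0.01 for p in pvals) <= 1

    def test_overlapping_regions_rejected(self, small_fragment_map):
        t = make_track(small_fragment_map, np.ones(14))
        with pytest.raises(ValueError):
            allelic_subdomain_test(
                t, t, GenomicInterval("chrT", 0, 5000), GenomicInterval("chrT", 4000, 9000)
            )


class TestCombinedSignalConservation:
    """With pure redistribution planted, the combined signal of the two
    sub-domains stays equal between alleles while its split shifts."""

    def test_headline_structural_property(self):
        spec = simulate.default_domain_spec()
        vp_bin = 132
        boosts = simulate.conserving_subtad_boosts(
            spec, vp_bin, "subtad", "telomeric", 2.0
        )
        window = NormalizationWindow(GenomicInterval(spec.chrom, 0, spec.chrom_length))
        mats = simulate.simulate_contact_matrix(
            spec, subtad_boost_by_allele=boosts, noise_dispersion=None
        )
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fmap = simulate.simulate_fragment_map(spec.chrom_length, seed=rng)
            sig = {}
            for allele in ("maternal", "paternal"):
                t = simulate.simulate_4c_counts(
                    mats[allele], vp_bin, 100_000, fmap, seed=rng, allele=allele
                )
                t = normalize_to_window(t, window)
                sig[allele] = subdomain_distribution(t, spec.partition).per_part_signal
            combined_mat = sig["maternal"][1] + sig["maternal"][2]
            combined_pat = sig["paternal"][1] + sig["paternal"][2]
            assert combined_mat == pytest.approx(combined_pat, rel=0.02)
            # the maternal share rises in the sub-TAD and falls telomeric
            assert sig["maternal"][1] > sig["paternal"][1]
            assert sig["maternal"][2] < sig["paternal"][2]
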