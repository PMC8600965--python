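import numpy as np
import pandas as pd
import pytest

from gdi import (EstimatorConfig, GraphConfig, TimeSeriesSet,
                 average_over_bin_widths, build_graph, conditional_entropy,
                 estimate_di, estimate_gdi, normalize_di,
                 select_conditioning_set)
from gdi.graph import combine_sign_votes


class TestSelectConditioningSet:
    def test_threshold_filtering(self):
        D = np.zeros((5, 5))
        D[2, 1], D[3, 1], D[4, 1] = 0.005, 0.02, 0.3
        assert select_conditioning_set(D, 0, 1, 0.01) == (3, 4)

    def test_all_zero_matrix_empty(self):
        assert select_conditioning_set(np.zeros((4, 4)), 0, 1, 0.01) == ()

    def test_zero_threshold_selects_all_others(self):
        assert select_conditioning_set(np.zeros((4, 4)), 0, 1, 0.0) == (2, 3)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            select_conditioning_set(np.zeros((3, 4)), 0, 1, 0.01)


class TestNormalizeDi:
    def test_endpoints(self):
        assert normalize_di(0.0, 0.5) == 0.0
        assert normalize_di(0.5, 0.5) == 1.0

    def test_clipping_warns(self):
        with pytest.warns(UserWarning):
            assert normalize_di(0.7, 0.5) == 1.0

    def test_degenerate_entropy_rejected(self):
        with pytest.raises(ValueError):
            normalize_di(0.1, 0.0)


class TestConditionalEntropy:
    def test_iid_bernoulli_matches_marginal_entropy(self, rng):
        p = 0.3
        y = (rng.random(200_000) < p).astype(float)
        ts = TimeSeriesSet(np.column_stack([y, y * 0]), kind="binary")
        h = conditional_entropy(ts, 0, 2)
        expected = -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert h == pytest.approx(expected, abs=0.005)

    def test_requires_binary(self, white_noise_series):
        with pytest.raises(ValueError):
            conditional_entropy(white_noise_series, 0, 1)


class TestEstimateDiGdi:
    def test_independent_channels_near_zero(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(3000, 2)))
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(bootstrap_iters=3, seed=0))
        assert abs(estimate_di(ts, 0, 1, cfg).value) < 0.05

    def test_noiseless_binary_copy_reaches_capacity(self, rng):
        x = (rng.random(4000) < 0.5).astype(float)
        y = np.r_[0.0, x[:-1]]
        ts = TimeSeriesSet(np.column_stack([x, y]), kind="binary")
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(bootstrap_iters=4, seed=0))
        di = estimate_di(ts, 0, 1, cfg).value
        assert di == pytest.approx(np.log(2), abs=0.07)
        # normalized by the target's conditional entropy this is ~1
        h = conditional_entropy(ts, 1, 1)
        assert normalize_di(di, h) == pytest.approx(1.0, abs=0.1)

    def test_empty_conditioning_equals_di(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(2000, 2)))
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(bootstrap_iters=2, seed=0))
        di = estimate_di(ts, 0, 1, cfg)
        gdi = estimate_gdi(ts, 0, 1, (), cfg)
        # same quantity, different seed substreams: statistically equal
        assert gdi.value == pytest.approx(di.value, abs=0.05)

    def test_self_edge_rejected(self, white_noise_series, quick_graph_cfg):
        with pytest.raises(ValueError):
            estimate_di(white_noise_series, 1, 1, quick_graph_cfg)


class TestBuildGraph:
    def test_independent_noise_graph_near_zero(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(2400, 2)))
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(bootstrap_iters=3, seed=1))
        g = build_graph(ts, cfg)
        assert len(g.edges) == 2
        for rec in g.edges.values():
            assert abs(rec.weight) < 0.06

    def test_graphical_thresholded_reduces_to_pairwise(self, rng):
        # a huge threshold empties every conditioning set, so graphical GDI
        # equals pairwise DI bit-for-bit under equal seeds
        x = rng.normal(size=2000)
        y = np.r_[0.0, 0.7 * x[:-1]] + 0.3 * rng.normal(size=2000)
        ts = TimeSeriesSet(np.column_stack([x, y, rng.normal(size=2000)]))
        est = EstimatorConfig(bootstrap_iters=2, seed=5)
        cfg = GraphConfig(M=1, estimator=est, conditioning_policy="di-thresholded",
                          di_threshold=1e9)
        g = build_graph(ts, cfg)
        for (j, k), rec in g.edges.items():
            assert rec.conditioning == ()
            direct = estimate_gdi(ts, j, k, (), cfg)
            assert rec.raw_gdi == direct.value

    def test_directed_edge_detected_with_sign(self, rng):
        x = rng.normal(size=3000)
        y = np.r_[0.0, -0.8 * x[:-1]] + 0.2 * rng.normal(size=3000)
        ts = TimeSeriesSet(np.column_stack([x, y]))
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(bootstrap_iters=3, seed=0))
        g = build_graph(ts, cfg)
        rec = g.edges[("1", "2")]
        assert rec.raw_gdi > 0.3
        assert rec.sign == -1 and rec.weight < 0
        assert g.edges[("2", "1")].raw_gdi < 0.1

    def test_deterministic_under_seed(self, rng):
        ts = TimeSeriesSet(rng.normal(size=(800, 2)))
        cfg = GraphConfig(M=1, estimator=EstimatorConfig(
            bootstrap_iters=2, seed=9))
        g1 = build_graph(ts, cfg)
        g2 = build_graph(ts, cfg)
        pd.testing.assert_frame_equal(g1.to_dataframe(), g2.to_dataframe())


class TestSignVotes:
    @pytest.mark.parametrize("votes,expected", [
        ([1, 1, -1], 1),
        ([1, -1], 0),
        ([-1, -1, -1], -1),
        ([], 0),
    ])
    def test_combination_rule(self, votes, expected):
        assert combine_sign_votes(votes) == expected


class TestAverageOverBinWidths:
    def test_consistent_widths_average_cleanly(self, rng):
        # strong excitatory 1 -> 2 spiking pair; both widths see the edge
        from gdi import NetworkSpec, gen_spiking_network

        spec = NetworkSpec(n_nodes=2, edges=[(1, 2, 0.9)])
        spikes = gen_spiking_network(spec, T=250.0, bin_width=0.02, seed=2,
                                     baseline=-1.8, gain=5.0)
        cfg = GraphConfig(M=2, estimator=EstimatorConfig(bootstrap_iters=3, seed=0),
                          conditioning_policy="di-thresholded",
                          bin_widths=(0.02, 0.04))
        g = average_over_bin_widths(spikes, cfg)
        rec = g.edges[("1", "2")]
        assert rec.sign == 1
        assert rec.weight > 0.01
        assert g.edges[("2", "1")].weight < rec.weight

    def test_needs_two_widths(self):
        spikes = pd.DataFrame({"unit": [1, 2], "time": [0.1, 0.2]})
        cfg = GraphConfig(bin_widths=(0.02,))
        with pytest.raises(ValueError):
            average_over_bin_widths(spikes, cfg)
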