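import numpy as np
import pytest

from gdi import (ClassifierSpec, EstimatorConfig, SamplePairSet, estimate_cmi,
                 estimate_kl, estimate_mi, fit_ratio_model, permute_block)


class _ConstantRatio:
    """Stub model returning a fixed log-ratio per test point."""

    def __init__(self, values_p, values_q):
        self._vp = np.asarray(values_p, dtype=float)
        self._vq = np.asarray(values_q, dtype=float)
        self._toggle = 0

    def log_ratio(self, x):
        out = self._vp if self._toggle == 0 else self._vq
        self._toggle ^= 1
        return out[: len(np.atleast_2d(x))]


class TestEstimateKl:
    def test_unit_ratio_gives_zero(self):
        model = _ConstantRatio(np.zeros(4), np.zeros(4))
        assert estimate_kl(np.zeros((4, 1)), np.zeros((4, 1)), model) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # L = e on both p points, L = 1 on both q points -> 1 - log 1 = 1 nat
        model = _ConstantRatio(np.ones(2), np.zeros(2))
        val = estimate_kl(np.zeros((2, 1)), np.zeros((2, 1)), model)
        assert val == pytest.approx(1.0)

    def test_empty_test_set_rejected(self):
        model = _ConstantRatio(np.ones(1), np.ones(1))
        with pytest.raises(ValueError):
            estimate_kl(np.empty((0, 1)), np.ones((2, 1)), model)

    def test_gaussian_shift_closed_form(self, rng):
        # KL(N(0,1) || N(1,1)) = 1/2 nat
        n = 5000
        p = rng.normal(0.0, 1.0, size=(n, 1))
        q = rng.normal(1.0, 1.0, size=(n, 1))
        spec = ClassifierSpec(hidden_layers=(32,), max_epochs=40)
        model = fit_ratio_model(p[: 2 * n // 3], q[: 2 * n // 3], spec, seed=0)
        val = estimate_kl(p[2 * n // 3:], q[2 * n // 3:], model)
        assert val == pytest.approx(0.5, abs=0.1)


class TestFitRatioModel:
    def test_chance_level_when_p_equals_q(self, rng, quick_classifier):
        x = rng.normal(size=(600, 2))
        model = fit_ratio_model(x[:300], x[300:], quick_classifier, seed=1)
        # log-ratio hovers near zero: the classifier is at chance
        assert abs(np.mean(model.log_ratio(rng.normal(size=(200, 2))))) < 0.35

    def test_ratio_clipped_when_separable(self, rng):
        spec = ClassifierSpec(hidden_layers=(16,), max_epochs=30, prob_clip=1e-2)
        p = rng.normal(10.0, 0.1, size=(300, 1))
        q = rng.normal(-10.0, 0.1, size=(300, 1))
        model = fit_ratio_model(p, q, spec, seed=0)
        cap = np.log((1 - 1e-2) / 1e-2)
        assert np.all(np.abs(model.log_ratio(np.vstack([p, q]))) <= cap + 1e-9)

    def test_deterministic_under_seed(self, rng, quick_classifier):
        p = rng.normal(size=(200, 2))
        q = rng.normal(0.5, 1, size=(200, 2))
        m1 = fit_ratio_model(p, q, quick_classifier, seed=42)
        m2 = fit_ratio_model(p, q, quick_classifier, seed=42)
        x = rng.normal(size=(50, 2))
        np.testing.assert_array_equal(m1.log_ratio(x), m2.log_ratio(x))

    def test_dimension_mismatch(self, rng, quick_classifier):
        with pytest.raises(ValueError):
            fit_ratio_model(rng.normal(size=(10, 2)), rng.normal(size=(10, 3)),
                            quick_classifier, seed=0)
        model = fit_ratio_model(rng.normal(size=(50, 2)),
                                rng.normal(size=(50, 2)), quick_classifier, seed=0)
        with pytest.raises(ValueError):
            model.log_ratio(rng.normal(size=(5, 4)))


def _pair_from(joint, seed=0):
    a_idx = np.array([0])
    return SamplePairSet(joint, permute_block(joint, a_idx, seed), a_idx)


class TestEstimateMi:
    def test_independent_blocks_near_zero(self, rng):
        joint = rng.normal(size=(1500, 2))
        cfg = EstimatorConfig(bootstrap_iters=4, seed=0,
                              classifier=ClassifierSpec(hidden_layers=(16,),
                                                        max_epochs=20))
        est = estimate_mi(_pair_from(joint), cfg)
        assert abs(est.value) < 0.05
        assert est.value == pytest.approx(np.mean(est.per_iteration))
        assert len(est.per_iteration) == 4

    def test_correlated_gaussian_closed_form(self, rng):
        rho = 0.6
        x = rng.normal(size=2500)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=2500)
        est = estimate_mi(_pair_from(np.column_stack([x, y])),
                          EstimatorConfig(bootstrap_iters=6, seed=0))
        assert est.value == pytest.approx(-0.5 * np.log(1 - rho ** 2), abs=0.05)

    def test_too_few_rows(self, quick_estimator):
        with pytest.raises(ValueError):
            estimate_mi(_pair_from(np.ones((2, 2))), quick_estimator)


class TestEstimateCmi:
    def test_empty_conditioning_reduces_to_mi(self, rng, quick_estimator):
        A = rng.normal(size=(300, 1))
        B = rng.normal(size=(300, 1))
        direct = estimate_mi(_pair_from(np.hstack([A, B]), quick_estimator.seed),
                             quick_estimator)
        reduced = estimate_cmi(A, B, None, quick_estimator)
        assert reduced.value == pytest.approx(direct.value)

    def test_markov_chain_conditional_independence(self, rng):
        # A -> Z -> B: conditional MI vanishes while marginal MI does not
        n = 6000
        A = (rng.random(n) < 0.5).astype(float)
        Z = np.where(rng.random(n) < 0.1, 1 - A, A)
        B = np.where(rng.random(n) < 0.1, 1 - Z, Z)
        cfg = EstimatorConfig(bootstrap_iters=5, seed=3)
        cmi = estimate_cmi(A[:, None], B[:, None], Z[:, None], cfg)
        mi = estimate_mi(_pair_from(np.column_stack([A, B]), 3), cfg)
        assert abs(cmi.value) < 0.03
        assert mi.value > 0.2

    def test_independent_of_everything(self, rng, quick_estimator):
        cmi = estimate_cmi(rng.normal(size=(400, 1)), rng.normal(size=(400, 1)),
                           rng.normal(size=(400, 2)), quick_estimator)
        assert abs(cmi.value) < 0.12
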