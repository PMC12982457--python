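"""Attribution suite: Shapley axioms, Integrated Gradients, Grad-CAM."""

import numpy as np
import pytest

from parkfuse._nn import Conv2d, Dense, ReLU, Sequential
from parkfuse.errors import ConfigError
from parkfuse.explain import (
    aggregate_by_modality,
    attribution_consistency,
    encoder_grad_fn,
    grad_cam,
    integrated_gradients,
    marginal_value_fn,
    replace_value_fn,
    shapley_exact,
    shapley_sampled,
    xai_feature_selection,
)


class TestShapleyExact:
    def test_two_player_hand_game(self):
        game = {(): 0.0, (0,): 1.0, (1,): 2.0, (0, 1): 4.0}
        res = shapley_exact(lambda s: game[s], 2)
        np.testing.assert_allclose(res.values, [1.5, 2.5])

    def test_efficiency_axiom(self, rng):
        w = rng.normal(size=6)
        x = rng.normal(size=6)
        vf = replace_value_fn(lambda v: float(v @ w + 0.3 * v[0] * v[2]), x, np.zeros(6))
        res = shapley_exact(vf, 6)
        assert abs(res.metadata["efficiency_gap"]) < 1e-6

    def test_additivity_on_linear_model(self):
        w = np.array([2.0, -1.0, 3.0])
        x = np.array([1.0, 2.0, 3.0])
        vf = replace_value_fn(lambda v: float(v @ w), x, np.zeros(3))
        np.testing.assert_allclose(shapley_exact(vf, 3).values, w * x, atol=1e-12)

    def test_symmetry_axiom(self):
        # players 0 and 1 are interchangeable
        vf = lambda s: float(len(s)) + (0.5 if (0 in s) == (1 in s) else 0.0)
        res = shapley_exact(vf, 3)
        assert res.values[0] == pytest.approx(res.values[1])

    def test_dummy_player_gets_zero(self):
        vf = lambda s: float(2.0 * (0 in s))  # player 1 contributes nothing
        res = shapley_exact(vf, 2)
        assert res.values[1] == pytest.approx(0.0)

    def test_feature_limit_redirects(self):
        with pytest.raises(ConfigError, match="shapley_sampled"):
            shapley_exact(lambda s: 0.0, 16)


class TestShapleySampled:
    def _toy(self, rng, n=8):
        w = rng.normal(size=n)
        x = rng.normal(size=n)
        f = lambda v: float(v @ w + 0.5 * v[0] * v[1])
        return replace_value_fn(f, x, np.zeros(n)), n

    def test_matches_exact_within_monte_carlo_error(self, rng):
        vf, n = self._toy(rng)
        exact = shapley_exact(vf, n)
        sampled = shapley_sampled(vf, n, n_permutations=3000, seed=1)
        spread = exact.values.max() - exact.values.min()
        assert np.abs(sampled.values - exact.values).max() < 0.05 * spread
        assert np.all(np.abs(sampled.values - exact.values)
                      <= np.maximum(3 * sampled.metadata["mc_se"], 1e-9))

    def test_error_shrinks_with_more_permutations(self, rng):
        vf, n = self._toy(rng)
        exact = shapley_exact(vf, n).values
        errs = []
        for n_perm in (50, 400, 3200):
            s = shapley_sampled(vf, n, n_permutations=n_perm, seed=2)
            errs.append(np.abs(s.values - exact).max())
        assert errs[2] < errs[0]

    def test_efficiency_by_construction(self, rng):
        vf, n = self._toy(rng)
        s = shapley_sampled(vf, n, n_permutations=40, seed=0)
        full, empty = vf(tuple(range(n))), vf(())
        assert s.values.sum() == pytest.approx(full - empty, abs=1e-9)

    def test_too_few_permutations_raise(self):
        with pytest.raises(ConfigError):
            shapley_sampled(lambda s: 0.0, 3, n_permutations=5)

    def test_rank_agreement_with_exact_on_tree_ensemble(self, rng):
        """Dual-route check on a gradient-boosted model: the permutation
        sampler against full enumeration with the marginal-expectation
        value function."""
        from scipy.stats import spearmanr

        from parkfuse.fusion import train_xgboost

        x = rng.normal(size=(80, 6))
        y = ((x[:, 0] + 0.8 * x[:, 3] - 0.5 * x[:, 5]) > 0).astype(int)
        model = train_xgboost(x, y, seed=0, n_estimators=20, max_depth=2)
        predict = lambda v: model.predict_proba(np.atleast_2d(v))[:, 1]
        vf = marginal_value_fn(predict, x[0], x[:40])
        exact = shapley_exact(vf, 6)
        sampled = shapley_sampled(vf, 6, n_permutations=400, seed=3)
        rho = spearmanr(exact.values, sampled.values).statistic
        assert rho >= 0.95


class TestIntegratedGradients:
    def test_linear_model_exact_at_any_step_count(self):
        w = np.array([3.0, -2.0])
        grad_fn = lambda x: (float(x @ w), w)
        for steps in (8, 16, 64):
            res = integrated_gradients(grad_fn, np.array([1.0, 1.0]),
                                       np.zeros(2), steps=steps)
            np.testing.assert_allclose(res.values, [3.0, -2.0], atol=1e-12)

    def test_baseline_equals_instance_gives_zeros(self):
        grad_fn = lambda x: (float((x**2).sum()), 2 * x)
        k = np.array([0.5, -0.3])
        res = integrated_gradients(grad_fn, k, k.copy(), steps=16)
        np.testing.assert_allclose(res.values, 0.0)

    def test_completeness_on_small_trained_network(self, rng):
        net = Sequential([Dense(4, 8), ReLU(), Dense(8, 1)])
        net.initialize(np.random.default_rng(0))

        def grad_fn(x):
            out = net.forward(x[None])
            g = net.backward(np.ones((1, 1)))
            return float(out[0, 0]), g[0]

        k = rng.normal(size=4)
        res = integrated_gradients(grad_fn, k, np.zeros(4), steps=128)
        assert abs(res.metadata["completeness_residual"]) < 1e-3

    def test_completeness_residual_shrinks_as_steps_double(self, rng):
        net = Sequential([Dense(3, 6), ReLU(), Dense(6, 1)])
        net.initialize(np.random.default_rng(1))

        def grad_fn(x):
            out = net.forward(x[None])
            g = net.backward(np.ones((1, 1)))
            return float(out[0, 0]), g[0]

        k = rng.normal(size=3) + 1.0
        residuals = []
        for steps in (16, 32, 64, 128):
            res = integrated_gradients(grad_fn, k, np.zeros(3), steps=steps)
            residuals.append(abs(res.metadata["completeness_residual"]))
        assert residuals[-1] <= residuals[0] + 1e-9

    def test_too_few_steps_raise(self):
        with pytest.raises(ConfigError):
            integrated_gradients(lambda x: (0.0, x), np.ones(2), np.zeros(2), steps=4)


class _TinyConvModel:
    """1x1-conv feature extractor + GAP + linear head, for Grad-CAM oracles."""

    def __init__(self, head_weight):
        self.features = Sequential([Conv2d(1, 1, 1)])
        self.features.layers[0].w.value[...] = 1.0
        self.head = Dense(1, 2)
        self.head.w.value[...] = 0.0
        self.head.w.value[0, 1] = head_weight

    def forward(self, x):
        h = self.features.forward(x)
        self._shape = h.shape
        return self.head.forward(h.mean(axis=(2, 3)))

    def backward(self, g):
        gz = self.head.backward(g)
        b, c, hh, ww = self._shape
        return self.features.backward(
            np.broadcast_to(gz[:, :, None, None], self._shape).copy() / (hh * ww))

    def zero_grad(self):
        for p in self.features.params() + self.head.params():
            p.grad[...] = 0.0


class TestGradCAM:
    def test_single_map_uniform_gradient_is_relu_of_map(self, rng):
        x = rng.normal(size=(6, 6))
        res = grad_cam(_TinyConvModel(+2.0), x, target_class=1)
        raw = res.metadata["raw_map"]
        expected = np.maximum(res.metadata["alpha"][0] * x, 0.0)
        np.testing.assert_allclose(raw, expected, atol=1e-12)
        assert (res.values >= 0).all()

    def test_negative_weighted_sum_clamps_to_zero(self, rng):
        x = np.abs(rng.normal(size=(6, 6)))  # positive map
        res = grad_cam(_TinyConvModel(-2.0), x, target_class=1)
        assert (res.values == 0).all()

    def test_no_spatial_layer_raises(self):
        class Flat:
            features = Sequential([Dense(4, 2)])

            def forward(self, x):
                return self.features.forward(x.reshape(1, -1))

            def backward(self, g):
                return self.features.backward(g)

            def zero_grad(self):
                pass

        with pytest.raises(ConfigError):
            grad_cam(Flat(), np.zeros((1, 1, 2, 2)), 0)

    def test_heatmap_shape_matches_input(self, rng):
        x = rng.normal(size=(10, 12))
        res = grad_cam(_TinyConvModel(1.0), x, target_class=1)
        assert res.values.shape == (10, 12)


class TestAggregation:
    SPANS = {"speech": (0, 32), "handwriting": (32, 96), "gait": (96, 160)}

    def test_all_mass_in_one_modality(self):
        phi = np.zeros(160)
        phi[100] = 5.0
        shares = aggregate_by_modality(phi, self.SPANS)
        assert shares == {"speech": 0.0, "handwriting": 0.0, "gait": 1.0}

    def test_uniform_magnitude_weights_by_span_size(self):
        shares = aggregate_by_modality(np.ones(160), self.SPANS)
        assert shares["speech"] == pytest.approx(0.2)
        assert shares["handwriting"] == pytest.approx(0.4)
        assert shares["gait"] == pytest.approx(0.4)

    def test_sign_invariance(self, rng):
        phi = rng.normal(size=160)
        a = aggregate_by_modality(phi, self.SPANS)
        b = aggregate_by_modality(-phi, self.SPANS)
        for m in a:
            assert a[m] == pytest.approx(b[m])

    def test_span_gap_raises(self):
        with pytest.raises(ConfigError):
            aggregate_by_modality(np.ones(10), {"a": (0, 4), "b": (6, 10)})


class TestConsistency:
    def test_identical_attributions_correlate_perfectly(self):
        prof = np.linspace(0, 1, 50)
        rep = attribution_consistency([prof, prof.copy(), prof.copy()])
        assert rep["mean"] == pytest.approx(1.0)
        assert rep["min"] == pytest.approx(1.0)

    def test_independent_random_attributions_near_zero(self, rng):
        folds = [rng.normal(size=100) for _ in range(4)]
        rep = attribution_consistency(folds)
        assert abs(rep["mean"]) < 0.3

    def test_input_validation(self):
        with pytest.raises(ConfigError):
            attribution_consistency([np.ones(5)])
        with pytest.raises(ConfigError):
            attribution_consistency([np.ones(1), np.ones(1)])


class TestFeatureSelection:
    def test_keeps_top_fraction_by_mean_abs(self):
        shap = np.array([[0.1, 5.0, 0.2, 3.0, 0.05]])
        keep = xai_feature_selection(shap, keep_fraction=0.4)
        np.testing.assert_array_equal(keep, [1, 3])

    def test_invalid_fraction_raises(self):
        with pytest.raises(ConfigError):
            xai_feature_selection(np.ones((1, 4)), keep_fraction=0.0)


class TestEncoderGradFn:
    def test_gradient_matches_finite_differences(self, rng):
        from parkfuse.handwriting import HandwritingEncoder, ResNetSpec

        model = HandwritingEncoder(ResNetSpec(stem_pool=4, stem_channels=2,
                                              stages=((4, 2),), blocks_per_stage=0))
        model.initialize(np.random.default_rng(0))
        fn = encoder_grad_fn(model, target_class=1)
        x = rng.normal(size=(16, 16))
        f0, g = fn(x)
        for idx in [(3, 4), (10, 11)]:
            e = np.zeros_like(x)
            e[idx] = 1e-5
            num = (fn(x + e)[0] - fn(x - e)[0]) / 2e-5
            assert abs(num - g[idx]) < 1e-4 * (1 + abs(num))
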