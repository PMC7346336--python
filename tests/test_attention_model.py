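import numpy as np
import pytest
from conftest import max_relative_gradient_error
from hypothesis import given, settings
from hypothesis import strategies as st

from attnrisk import (
    AttentionClassifier,
    AttentionParams,
    ModelConfig,
    compute_attention,
    fit_attention_model,
    gate_input,
)
from attnrisk.attention_model import ModelError


def zeroed_model(m=4, n_hidden_layers=1, hidden_width=4, seed=0, **kw):
    cfg = ModelConfig(n_hidden_layers=n_hidden_layers, hidden_width=hidden_width, seed=seed, **kw)
    model = AttentionClassifier(m, cfg)
    for v in model.params.values():
        v[:] = 0.0
    return model


class TestComputeAttention:
    def test_zero_parameters_give_uniform(self):
        params = AttentionParams(np.zeros((4, 4)), np.zeros(4))
        alpha = compute_attention(np.array([3.0, -1.0, 0.0, 7.0]), params)
        np.testing.assert_allclose(alpha, 0.25)

    def test_log_three_bias_hand_case(self):
        params = AttentionParams(np.zeros((2, 2)), np.array([0.0, np.log(3.0)]))
        alpha = compute_attention(np.array([5.0, -2.0]), params)
        np.testing.assert_allclose(alpha, [0.25, 0.75], atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        x = rng.standard_normal(3)
        a1 = compute_attention(x, AttentionParams(W, b))
        a2 = compute_attention(x, AttentionParams(W, b + 17.3))
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_extreme_logits_no_overflow(self):
        params = AttentionParams(np.zeros((2, 2)), np.array([0.0, 5000.0]))
        alpha = compute_attention(np.zeros(2), params)
        assert np.isfinite(alpha).all() and alpha.sum() == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        params = AttentionParams(np.zeros((3, 3)), np.zeros(3))
        with pytest.raises(ModelError):
            compute_attention(np.zeros(4), params)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_simplex_property(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 10))
        params = AttentionParams(rng.standard_normal((m, m)), rng.standard_normal(m))
        alpha = compute_attention(rng.standard_normal(m), params)
        assert abs(alpha.sum() - 1.0) < 1e-9
        assert np.all(alpha > 0) and np.all(alpha < 1)


class TestGateInput:
    def test_uniform_attention_scales_by_inverse_m(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(gate_input(x, np.full(4, 0.25)), x / 4)

    def test_one_hot_selects_single_feature(self):
        x = np.array([5.0, 6.0, 7.0])
        alpha = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(gate_input(x, alpha), [0.0, 6.0, 0.0])

    def test_zero_input_annihilates(self):
        np.testing.assert_array_equal(gate_input(np.zeros(3), np.full(3, 1 / 3)), np.zeros(3))

    def test_length_mismatch(self):
        with pytest.raises(ModelError):
            gate_input(np.zeros(3), np.full(2, 0.5))


class TestForward:
    def test_all_zero_parameters_give_half(self):
        model = zeroed_model()
        probs, alpha = model.forward(np.random.default_rng(0).standard_normal((5, 4)))
        np.testing.assert_allclose(probs, 0.5)
        np.testing.assert_allclose(alpha.alpha, 0.25)

    def test_uniform_attention_equivalence(self):
        """Zero attention parameters = a plain MLP applied to X/m."""
        rng = np.random.default_rng(1)
        m = 6
        cfg = ModelConfig(n_hidden_layers=2, hidden_width=8, seed=5)
        attn = AttentionClassifier(m, cfg, use_attention=True)
        attn.set_attention_to_zero()
        plain = AttentionClassifier(m, cfg, use_attention=False)
        for k in plain.params:
            plain.params[k] = attn.params[k].copy()
        X = rng.standard_normal((100, m)) * 3
        p_attn, _ = attn.forward(X)
        p_plain, _ = plain.forward(X / m)
        np.testing.assert_allclose(p_attn, p_plain, atol=1e-12)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        cfg = ModelConfig(seed=0)
        model = AttentionClassifier(5, cfg)
        probs, _ = model.forward(rng.standard_normal((50, 5)) * 10)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_non_finite_input_rejected(self):
        model = zeroed_model()
        with pytest.raises(ModelError):
            model.forward(np.array([[np.nan, 0, 0, 0]]))


class TestComputeLoss:
    def test_zero_model_loss_is_ln_two(self):
        model = zeroed_model()
        X = np.random.default_rng(0).standard_normal((10, 4))
        Y = np.array([1, 0] * 5)
        assert model.compute_loss(X, Y, lambda_=0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_fit_loss_near_zero(self):
        # output bias pushed to +inf surrogate: huge bias gives prob ~ 1
        model = zeroed_model(m=2, hidden_width=2)
        model.params["b1"][:] = 50.0
        X = np.zeros((4, 2))
        Y = np.ones(4)
        assert model.compute_loss(X, Y, lambda_=0.0) <= 1.1e-7

    def test_penalty_linearity_in_lambda(self):
        rng = np.random.default_rng(3)
        cfg = ModelConfig(n_hidden_layers=1, hidden_width=4, seed=7)
        model = AttentionClassifier(5, cfg)
        X = rng.standard_normal((8, 5))
        Y = rng.integers(0, 2, 8)
        theta_sq = sum(
            float(np.sum(v * v))
            for k, v in model.params.items()
            if k in ("attn_W", "attn_b", "W0", "W1")
        )
        l1 = model.compute_loss(X, Y, lambda_=0.25)
        l2 = model.compute_loss(X, Y, lambda_=0.75)
        assert l2 - l1 == pytest.approx(0.5 * theta_sq, rel=1e-10)

    def test_biases_not_penalized(self):
        model = zeroed_model()
        model.params["b0"][:] = 100.0
        X = np.zeros((2, 4))
        Y = np.array([0, 1])
        # only bias is nonzero: penalty term must contribute nothing
        assert model.compute_loss(X, Y, lambda_=1e6) == model.compute_loss(X, Y, lambda_=0.0)

    def test_non_binary_labels_rejected(self):
        model = zeroed_model()
        with pytest.raises(ModelError):
            model.compute_loss(np.zeros((2, 4)), np.array([0.5, 1.0]))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(n_hidden_layers=1, hidden_width=4, lambda_=0.001, seed=13)
        model = AttentionClassifier(5, cfg)
        X = rng.standard_normal((8, 5))
        Y = rng.integers(0, 2, 8)
        assert max_relative_gradient_error(model, X, Y) < 1e-5

    def test_gradient_check_deeper_network(self):
        rng = np.random.default_rng(23)
        cfg = ModelConfig(n_hidden_layers=3, hidden_width=6, lambda_=0.01, seed=29)
        model = AttentionClassifier(4, cfg)
        X = rng.standard_normal((6, 4))
        Y = rng.integers(0, 2, 6)
        assert max_relative_gradient_error(model, X, Y) < 1e-5

    def test_gradient_check_without_attention(self):
        rng = np.random.default_rng(31)
        cfg = ModelConfig(n_hidden_layers=2, hidden_width=5, seed=37)
        model = AttentionClassifier(5, cfg, use_attention=False)
        X = rng.standard_normal((8, 5))
        Y = rng.integers(0, 2, 8)
        assert max_relative_gradient_error(model, X, Y) < 1e-5


class TestFit:
    def test_separable_blobs_reach_perfect_training_accuracy(self, blobs_cohort):
        # independent check that the toy set is linearly separable
        from attnrisk.baselines import fit_logistic

        lr = fit_logistic(blobs_cohort, l2=1e-6)
        assert (lr.predict(blobs_cohort.X).labels == blobs_cohort.Y).mean() == 1.0

        cfg = ModelConfig(n_hidden_layers=1, hidden_width=8, epochs=150, patience=0, seed=0)
        model = fit_attention_model(blobs_cohort, cfg)
        pred = model.predict(blobs_cohort.X)
        assert (pred.labels == blobs_cohort.Y).mean() == 1.0

    def test_huge_penalty_collapses_weights_and_attention(self, blobs_cohort):
        cfg = ModelConfig(
            n_hidden_layers=1,
            hidden_width=8,
            lambda_=1e6,
            epochs=500,
            patience=0,
            seed=1,
        )
        model = fit_attention_model(blobs_cohort, cfg)
        for key in ("attn_W", "W0", "W1"):
            assert np.linalg.norm(model.params[key]) < 1e-2
        _, alpha = model.forward(blobs_cohort.X)
        np.testing.assert_allclose(alpha.alpha, 0.5, atol=1e-3)

    def test_same_seed_bit_identical_parameters(self, blobs_cohort):
        cfg = ModelConfig(epochs=20, seed=5)
        m1 = fit_attention_model(blobs_cohort, cfg)
        m2 = fit_attention_model(blobs_cohort, ModelConfig(epochs=20, seed=5))
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_training_loss_decreases(self, blobs_cohort):
        cfg = ModelConfig(epochs=30, patience=0, seed=2)
        model = fit_attention_model(blobs_cohort, cfg)
        hist = model.history["train_loss"]
        init = AttentionClassifier(blobs_cohort.m, cfg).compute_loss(
            blobs_cohort.X, blobs_cohort.Y
        )
        assert hist[-1] < init

    def test_fitted_loss_nondecreasing_in_lambda(self, blobs_cohort):
        losses = []
        for lam in (0.0, 0.1, 10.0):
            cfg = ModelConfig(
                n_hidden_layers=1, hidden_width=8, lambda_=lam, epochs=100, patience=0, seed=3
            )
            model = fit_attention_model(blobs_cohort, cfg)
            losses.append(model.compute_loss(blobs_cohort.X, blobs_cohort.Y, lambda_=lam))
        assert losses[0] <= losses[1] <= losses[2]

    def test_single_class_training_rejected(self):
        from attnrisk import PatientCohort

        cohort = PatientCohort(np.random.default_rng(0).standard_normal((20, 2)), ["a", "b"], np.ones(20, dtype=int))
        with pytest.raises(ModelError):
            fit_attention_model(cohort, ModelConfig(epochs=1))


class TestPredict:
    @pytest.mark.parametrize(
        "prob, expected", [(0.7, 1), (0.5, 0), (0.49, 0)]
    )
    def test_strict_threshold_rule(self, prob, expected):
        model = zeroed_model(m=2, hidden_width=2)
        # drive the output bias so sigmoid(b) == prob exactly
        model.params["b1"][:] = np.log(prob / (1 - prob))
        pred = model.predict(np.zeros((1, 2)), threshold=0.5)
        assert pred.probs[0] == pytest.approx(prob)
        assert pred.labels[0] == expected

    def test_threshold_out_of_range(self):
        model = zeroed_model()
        with pytest.raises(ModelError):
            model.predict(np.zeros((1, 4)), threshold=1.5)


class TestSerialization:
    def test_round_trip_reproduces_forward(self, tmp_path, blobs_cohort):
        cfg = ModelConfig(epochs=10, seed=4)
        model = fit_attention_model(blobs_cohort, cfg)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = AttentionClassifier.load(path)
        p1, a1 = model.forward(blobs_cohort.X)
        p2, a2 = loaded.forward(blobs_cohort.X)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        np.testing.assert_allclose(a1.alpha, a2.alpha, atol=1e-12)
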