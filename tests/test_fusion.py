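"""Dual-branch network: building blocks, gradients, training behaviour."""

import numpy as np
import pytest

from srpnet import (
    FeatureTable,
    FusionClassifier,
    FusionConfig,
    LabelVector,
    attention_fuse,
    fcn_forward,
    generate_cohort,
    minmax_normalize,
    self_attention,
    separable_spec,
)
from srpnet.fusion import init_params, loss_and_grads, stratified_split


@pytest.fixture
def tiny_params():
    cfg = FusionConfig(embed_dim=4, attention_dim=3, fcn_hidden=5,
                       fusion_dim=4, n_categories=3)
    return init_params(6, cfg, np.random.default_rng(0)), cfg


class TestSelfAttention:
    def test_single_token_returns_projected_v_row(self, tiny_params):
        params, _ = tiny_params
        tok = np.random.default_rng(1).random((1, 4))
        out = self_attention(tok, params)
        expected = (tok @ params["Wv"]) @ params["Wtp"] + params["btp"]
        np.testing.assert_allclose(out, expected[0], atol=1e-12)

    def test_zero_input_gives_constant_output(self, tiny_params):
        params, _ = tiny_params
        out = self_attention(np.zeros((5, 4)), params)
        # Q=K=V=0 so attention output is 0; only the projection bias remains
        np.testing.assert_allclose(out, params["btp"], atol=1e-12)

    def test_attention_rows_sum_to_one(self, tiny_params):
        from srpnet.fusion import _forward

        params, _ = tiny_params
        X = np.random.default_rng(2).random((7, 6))
        A = _forward(X, params, "learned")["A"]
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-12)

    def test_shape_mismatch_named(self, tiny_params):
        params, _ = tiny_params
        with pytest.raises(ValueError, match="W_Q"):
            self_attention(np.zeros((3, 9)), params)


class TestFcnForward:
    def test_relu_behaviour(self):
        params = {
            "W1": np.eye(2),
            "b1": np.zeros(2),
            "W2": np.eye(2),
            "b2": np.zeros(2),
        }
        out = fcn_forward(np.array([-1.0, 2.0]), params)
        np.testing.assert_allclose(out, [0.0, 2.0])

    def test_zero_input_zero_bias_gives_zero(self, tiny_params):
        params, _ = tiny_params
        params = dict(params, b1=np.zeros_like(params["b1"]), b2=np.zeros_like(params["b2"]))
        np.testing.assert_allclose(fcn_forward(np.zeros(6), params), 0.0, atol=1e-12)

    def test_output_width_is_fusion_dim(self, tiny_params):
        params, cfg = tiny_params
        out = fcn_forward(np.random.default_rng(0).random((9, 6)), params)
        assert out.shape == (9, cfg.fusion_dim)


class TestAttentionFuse:
    def test_equal_embeddings_gate_half_half(self, tiny_params):
        params, _ = tiny_params
        h = np.random.default_rng(3).random((5, 4))
        _, gates = attention_fuse(h, h.copy(), params)
        np.testing.assert_allclose(gates, 0.5, atol=1e-12)

    def test_gates_nonnegative_and_sum_to_one(self, tiny_params):
        params, _ = tiny_params
        rng = np.random.default_rng(4)
        _, gates = attention_fuse(rng.normal(size=(50, 4)), rng.normal(size=(50, 4)), params)
        assert (gates >= 0).all()
        np.testing.assert_allclose(gates.sum(axis=1), 1.0, atol=1e-9)

    def test_attention_only_limit_uses_transformer_branch(self, tiny_params):
        params, _ = tiny_params
        rng = np.random.default_rng(5)
        ht, hc = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        fused, gates = attention_fuse(ht, hc, params, gate_mode="attention_only")
        np.testing.assert_allclose(gates[:, 0], 1.0)
        np.testing.assert_allclose(fused, ht @ params["WL"] + params["bL"], atol=1e-12)

    def test_branch_shape_mismatch_rejected(self, tiny_params):
        params, _ = tiny_params
        with pytest.raises(ValueError, match="shape"):
            attention_fuse(np.zeros((2, 4)), np.zeros((3, 4)), params)


class TestGradients:
    @pytest.mark.parametrize("gate_mode", ["learned", "fcn_only", "attention_only"])
    def test_backprop_matches_finite_differences(self, gate_mode):
        rng = np.random.default_rng(0)
        cfg = FusionConfig(embed_dim=5, attention_dim=4, fcn_hidden=6,
                           fusion_dim=5, n_categories=3)
        params = init_params(4, cfg, rng)
        X = rng.random((3, 4))
        y = rng.integers(0, 3, 3)
        _, grads = loss_and_grads(params, X, y, gate_mode)
        eps = 1e-6
        for key in ("E", "Wq", "Wk", "Wv", "W1", "W2", "WL", "Wo", "wa", "Wg"):
            v = params[key]
            flat = v.reshape(-1)
            for idx in np.random.default_rng(1).choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, y, gate_mode)
                flat[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, y, gate_mode)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[idx]
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-4)


@pytest.fixture(scope="module")
def separable_fit():
    table, labels, _ = generate_cohort(separable_spec(1200, seed=1))
    table, _ = minmax_normalize(table)
    table = table.select([f"risk{i}" for i in range(1, 7)])
    cfg = FusionConfig(epochs=40, seed=1)
    return table, labels, FusionClassifier(table, labels, cfg).fit()


class TestTraining:
    def test_trace_length_equals_epochs(self, separable_fit):
        _, _, res = separable_fit
        assert len(res.trace.losses) == 40
        assert len(res.trace.heldout_precision) == 40
        assert np.isfinite(res.trace.losses).all()

    def test_same_seed_identical_trace(self):
        table, labels, _ = generate_cohort(separable_spec(600, seed=2))
        table, _ = minmax_normalize(table)
        cfg = FusionConfig(epochs=5, seed=3)
        r1 = FusionClassifier(table, labels, cfg).fit()
        r2 = FusionClassifier(table, labels, cfg).fit()
        assert r1.trace.losses == r2.trace.losses
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])

    def test_loss_moving_average_non_increasing_on_separable_data(self, separable_fit):
        _, _, res = separable_fit
        losses = np.array(res.trace.losses)
        window = 10
        ma = np.convolve(losses, np.ones(window) / window, mode="valid")
        assert (np.diff(ma) <= 1e-6).all()

    def test_gate_coefficients_sum_to_one_for_every_subject(self, separable_fit):
        table, _, res = separable_fit
        gates = res.gates(table)
        np.testing.assert_allclose(gates.sum(axis=1), 1.0, atol=1e-6)

    def test_rare_category_split_error(self):
        table = FeatureTable(
            values=np.random.default_rng(0).random((10, 2)),
            feature_names=["a", "b"], feature_kinds=["continuous"] * 2,
            normalized=True,
        )
        labels = LabelVector(codes=np.array([0] * 9 + [1]), category_names=["x", "y"])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too few"):
            stratified_split(np.array([0] * 50 + [1]), 0.0001, rng)
        # but a 9/1 cohort trains fine at 80/20 since round(0.8) >= 1
        FusionClassifier(table, labels, FusionConfig(epochs=1, seed=0)).fit()

    def test_unnormalized_table_rejected(self):
        table = FeatureTable(
            values=np.random.default_rng(0).random((20, 2)) * 10,
            feature_names=["a", "b"], feature_kinds=["continuous"] * 2,
        )
        labels = LabelVector(codes=np.tile([0, 1], 10), category_names=["x", "y"])
        with pytest.raises(ValueError, match="normalized"):
            FusionClassifier(table, labels)


class TestPrediction:
    def test_probability_rows_sum_to_one(self, separable_fit):
        table, _, res = separable_fit
        probs = res.predict_proba(table)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_consistent_with_labels(self, separable_fit):
        table, _, res = separable_fit
        probs = res.predict_proba(table)
        np.testing.assert_array_equal(res.predict(table), probs.argmax(axis=1))

    def test_zero_weight_binary_model_predicts_half(self):
        cfg = FusionConfig(embed_dim=2, attention_dim=2, fcn_hidden=2,
                           fusion_dim=2, n_categories=2)
        params = {k: np.zeros_like(v) for k, v in
                  init_params(3, cfg, np.random.default_rng(0)).items()}
        from srpnet.fusion import _forward

        probs = _forward(np.random.default_rng(1).random((4, 3)), params, "learned")["probs"]
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_checkpoint_roundtrip(self, tmp_path, separable_fit):
        from srpnet import FusionResults

        table, _, res = separable_fit
        res.save(tmp_path / "ckpt.npz")
        params, meta = FusionResults.load_params(tmp_path / "ckpt.npz")
        for k in res.params:
            np.testing.assert_array_equal(params[k], res.params[k])
        assert meta["feature_names"] == table.feature_names

    def test_summary_mentions_heldout_precision(self, separable_fit):
        _, _, res = separable_fit
        assert "held-out micro precision" in res.summary()


class TestAblations:
    def test_named_ablations_run_and_gate_is_forced(self):
        table, labels, _ = generate_cohort(separable_spec(600, seed=4))
        table, _ = minmax_normalize(table)
        cfg = FusionConfig(epochs=3, seed=4)
        for gm, col in [("fcn_only", 0), ("attention_only", 1)]:
            res = FusionClassifier(table, labels, cfg, gate_mode=gm).fit()
            gates = res.gates(table)
            np.testing.assert_allclose(gates[:, col], 0.0)
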