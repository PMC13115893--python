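"""Gated Transformer-CNN fusion model: arithmetic, training, evaluation."""

import numpy as np
import pytest

from conftest import separable_data
from oamethyl.fusion import (
    FusionModelConfig,
    TransCNN,
    ablation_compare,
    evaluate,
    evaluate_positive_only,
    gate_contribution,
    gated_fusion,
    positive_only_accuracy,
    train_model,
)
from oamethyl.nn.autograd import Tensor, no_grad
from oracles import auc_rank_oracle, gated_fusion_oracle


def small_config(**over):
    base = dict(d_model=8, cnn_out=8, fusion_dim=8, n_heads=2, n_layers=1,
                ff_dim=16, kernel_sizes=(3, 3), cnn_channels=(6,),
                dropout=0.0, max_epochs=5, patience=3, seed=0)
    base.update(over)
    return FusionModelConfig(**base)


class TestArchitectureContracts:
    def test_branch_output_shapes(self):
        m = TransCNN(12, small_config())
        with no_grad():
            tokens = m.embed(Tensor(np.random.default_rng(0).random((4, 12))))
            p_a = m.attention_branch(tokens)
            p_b = m.convolution_branch(tokens)
        assert p_a.shape == (4, 8)
        assert p_b.shape == (4, 8)

    def test_heads_must_divide_d_model(self):
        with pytest.raises(ValueError, match="divide"):
            small_config(d_model=10, n_heads=3)

    def test_kernel_wider_than_sequence_rejected(self):
        m = TransCNN(2, small_config(kernel_sizes=(3, 3)))
        with pytest.raises(ValueError, match="kernel"):
            with no_grad():
                m.forward(Tensor(np.zeros((1, 2))))

    def test_feature_count_mismatch_rejected(self):
        m = TransCNN(12, small_config())
        with pytest.raises(ValueError, match="features"):
            with no_grad():
                m.forward(Tensor(np.zeros((1, 10))))

    def test_attention_rows_sum_to_one(self):
        m = TransCNN(6, small_config())
        with no_grad():
            m.forward(Tensor(np.random.default_rng(1).random((2, 6))))
        attn = m.encoder_layers[0].attn.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)

    def test_attention_branch_permutation_equivariance(self):
        # permuting tokens together with their positional parameters
        # leaves the pooled attention output unchanged at initialization
        m = TransCNN(10, small_config())
        x = np.random.default_rng(2).random((3, 10))
        perm = np.random.default_rng(3).permutation(10)
        with no_grad():
            ref = m.attention_branch(m.embed(Tensor(x))).data
        for p in (m.embedding.value_weight, m.embedding.value_bias,
                  m.embedding.position):
            p.data = p.data[perm]
        with no_grad():
            out = m.attention_branch(m.embed(Tensor(x[:, perm]))).data
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_constant_input_gives_position_independent_conv_maps(self):
        cfg = small_config(kernel_sizes=(3,), cnn_channels=())
        m = TransCNN(9, cfg)
        # flatten position/bias structure so tokens are identical
        m.embedding.position.data[:] = 0.1
        m.embedding.value_bias.data[:] = 0.0
        m.embedding.value_weight.data[:] = m.embedding.value_weight.data[0]
        with no_grad():
            tokens = m.embed(Tensor(np.full((1, 9), 0.5)))
            fmap = m.conv_layers[0](tokens).data
        inner = fmap[0, 1:-1, :]  # edge positions see zero padding
        np.testing.assert_allclose(inner - inner[0], 0.0, atol=1e-12)


class TestGatedFusion:
    def test_injected_gate_boundaries(self):
        rng = np.random.default_rng(0)
        p_a, p_b = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        g = np.ones((2, 4))
        np.testing.assert_allclose(g * p_a + (1 - g) * p_b, p_a)
        g = np.full((2, 4), 0.5)
        np.testing.assert_allclose(g * p_a + (1 - g) * p_b, (p_a + p_b) / 2)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            F, H = 4, 4
            p_a, p_b = rng.normal(size=(3, F)), rng.normal(size=(3, F))
            W1, b1 = rng.normal(size=(2 * F, H)), rng.normal(size=H)
            W2, b2 = rng.normal(size=(H, F)), rng.normal(size=F)
            fused, g = gated_fusion(p_a, p_b, W1, b1, W2, b2)
            fused_ref, g_ref = gated_fusion_oracle(p_a, p_b, W1, b1, W2, b2)
            np.testing.assert_allclose(fused, fused_ref, atol=1e-12)
            np.testing.assert_allclose(g, g_ref, atol=1e-12)

    def test_fused_is_convex_combination(self):
        rng = np.random.default_rng(2)
        p_a, p_b = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        W1, b1 = rng.normal(size=(12, 6)), rng.normal(size=6)
        W2, b2 = rng.normal(size=(6, 6)), rng.normal(size=6)
        fused, g = gated_fusion(p_a, p_b, W1, b1, W2, b2)
        lo, hi = np.minimum(p_a, p_b), np.maximum(p_a, p_b)
        assert (fused >= lo - 1e-12).all() and (fused <= hi + 1e-12).all()
        assert (g > 0).all() and (g < 1).all()

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal width"):
            gated_fusion(np.zeros((1, 3)), np.zeros((1, 4)),
                         np.zeros((7, 2)), np.zeros(2), np.zeros((2, 3)),
                         np.zeros(3))


class TestTraining:
    def test_separable_data_reaches_high_auc(self, tiny_fusion_config):
        X, y = separable_data(seed=4)
        model, hist = train_model(X, y, tiny_fusion_config)
        m = evaluate(model, X, y)
        assert m.auc >= 0.95

    def test_same_seed_reproduces_weights(self, tiny_fusion_config):
        X, y = separable_data(seed=5)
        cfg = FusionModelConfig(**{**tiny_fusion_config.__dict__,
                                   "max_epochs": 6})
        m1, _ = train_model(X, y, cfg)
        m2, _ = train_model(X, y, cfg)
        for a, b in zip(m1.state(), m2.state()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, tiny_fusion_config):
        X, _ = separable_data()
        with pytest.raises(ValueError, match="classes"):
            train_model(X, np.zeros(len(X), dtype=int), tiny_fusion_config)

    def test_nonfinite_features_rejected(self, tiny_fusion_config):
        X, y = separable_data()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_model(X, y, tiny_fusion_config)


class TestEvaluation:
    class _Stub:
        """Fixed-score model standing in for a trained classifier."""

        is_trained = True

        def __init__(self, scores):
            self.scores = np.asarray(scores, dtype=float)

        def predict_proba(self, X):
            return self.scores[: len(X)]

        def predict(self, X):
            return (self.predict_proba(X) >= 0.5).astype(int)

    def test_perfect_predictor(self):
        model = self._Stub([0.9, 0.8, 0.1, 0.2])
        m = evaluate(model, np.zeros((4, 2)), [1, 1, 0, 0])
        assert (m.acc, m.f1, m.auc) == (1.0, 1.0, 1.0)

    def test_one_misranked_pair_gives_auc_075(self):
        model = self._Stub([0.9, 0.15, 0.1, 0.2])
        m = evaluate(model, np.zeros((4, 2)), [1, 1, 0, 0])
        assert m.auc == 0.75
        assert m.auc == auc_rank_oracle([1, 1, 0, 0], model.scores)

    def test_auc_equals_rank_oracle_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # ties likely
            m = evaluate(self._Stub(scores), np.zeros((n, 1)), y)
            assert abs(m.auc - auc_rank_oracle(y, scores)) < 1e-12

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            m = evaluate(self._Stub([0.9, 0.8]), np.zeros((2, 1)), [1, 1])
        assert m.auc is None

    def test_positive_only_accuracy_values(self):
        assert positive_only_accuracy(59, 62) == 0.9516
        assert positive_only_accuracy(5, 5) == 1.0
        assert positive_only_accuracy(0, 5) == 0.0

    def test_positive_only_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            positive_only_accuracy(0, 0)

    def test_evaluate_positive_only_counts(self, tiny_fusion_config):
        X, y = separable_data(seed=6)
        model, _ = train_model(X, y, tiny_fusion_config)
        n_correct, n_total, acc = evaluate_positive_only(model, X[y == 1])
        assert n_total == int((y == 1).sum())
        assert acc == positive_only_accuracy(n_correct, n_total)
        assert n_correct / n_total > 0.8


class TestGateStatistics:
    def test_complementarity_exact(self, tiny_fusion_config):
        X, y = separable_data(seed=7)
        model, _ = train_model(X, y, tiny_fusion_config)
        rec = gate_contribution(model, X)
        assert rec.mean_transformer_weight + rec.mean_cnn_weight == 1.0
        assert (rec.g > 0).all() and (rec.g < 1).all()
        assert rec.g.shape == (len(X), tiny_fusion_config.fusion_dim)

    def test_untrained_model_rejected(self):
        model = TransCNN(6, small_config())
        with pytest.raises(ValueError, match="trained"):
            gate_contribution(model, np.zeros((2, 6)))


class TestAblation:
    def test_four_variants_with_shared_split(self, tiny_fusion_config):
        X, y = separable_data(seed=9)
        cfg = FusionModelConfig(**{**tiny_fusion_config.__dict__,
                                   "max_epochs": 10})
        table = ablation_compare(X, y, cfg)
        assert set(table) == {"gated", "concat", "transformer", "cnn"}
        for m in table.values():
            assert 0.0 <= m.acc <= 1.0
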