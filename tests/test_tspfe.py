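import dataclasses
import warnings

import numpy as np
import pytest

from tspnet import _autograd as ag
from tspnet._autograd import Tensor
from tspnet.backbone import desk_config
from tspnet.model import TSPNet
from tspnet.tspfe import (TSPFE, ClassifierHead, cross_entropy_from_logits,
                          cross_entropy_loss, gated_features,
                          normalize_similarity, orthogonalize,
                          parallel_project, similarity_matrix)


def brute_similarity(x, p, d):
    """Loop-based Q = (PX)ᵀ D (PX) oracle."""
    h, w = x.shape
    px = np.zeros((h, w))
    for i in range(h):
        for j in range(h):
            px[i] += p[i, j] * x[j]
    q = np.zeros((w, w))
    for a in range(w):
        for b in range(w):
            q[a, b] = sum(px[k, a] * d[k] * px[k, b] for k in range(h))
    return q


class TestOrthogonalize:
    def test_zero_generator_is_identity(self):
        np.testing.assert_allclose(orthogonalize(np.zeros((5, 5))), np.eye(5))

    def test_quarter_turn_rotation(self):
        theta = np.pi / 2
        a = np.array([[0.0, theta / 2], [-theta / 2, 0.0]])
        # skew part is [[0, θ], [−θ, 0]]; exp = [[cos θ, sin θ], [−sin θ, cos θ]]
        p = orthogonalize(a)
        np.testing.assert_allclose(p, [[0, 1], [-1, 0]], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_orthogonal_for_random_generators(self, seed):
        a = np.random.default_rng(seed).normal(size=(6, 6)) * 2
        p = orthogonalize(a)
        assert np.abs(p.T @ p - np.eye(6)).max() < 1e-5

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            orthogonalize(np.zeros((2, 3)))


class TestSimilarityMatrix:
    def test_gram_matrix_when_identity(self, rng):
        x = rng.normal(size=(3, 4))
        q = similarity_matrix(x, np.eye(3), np.ones(3))
        np.testing.assert_allclose(q, x.T @ x, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(q) > -1e-10)   # PSD Gram

    def test_orthogonal_columns_give_diagonal(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        q = similarity_matrix(x, np.eye(3), np.ones(3))
        np.testing.assert_allclose(q, np.diag([1.0, 4.0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(3, 4))
        p = orthogonalize(rng.normal(size=(3, 3)))
        d = rng.normal(size=3)
        np.testing.assert_allclose(similarity_matrix(x, p, d),
                                   brute_similarity(x, p, d), atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            similarity_matrix(rng.normal(size=(3, 4)), np.eye(2), np.ones(2))


class TestNormalizeSimilarity:
    def test_columns_sum_to_one(self, rng):
        q = rng.normal(size=(5, 5))
        qc, qr = normalize_similarity(q)
        np.testing.assert_allclose(qc.sum(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(qr.sum(axis=0), 1.0, atol=1e-6)

    def test_zero_matrix_gives_uniform(self):
        qc, qr = normalize_similarity(np.zeros((4, 4)))
        np.testing.assert_allclose(qc, 0.25)
        np.testing.assert_allclose(qr, 0.25)

    def test_hand_evaluated_2x2(self):
        q = np.array([[0.0, np.log(3.0)], [0.0, 0.0]])
        qc, _ = normalize_similarity(q)
        np.testing.assert_allclose(qc[:, 1], [0.75, 0.25], atol=1e-12)

    def test_transposing_q_swaps_branches(self, rng):
        q = rng.normal(size=(6, 6))
        qc, qr = normalize_similarity(q)
        qc_t, qr_t = normalize_similarity(q.T)
        np.testing.assert_allclose(qc_t, qr)
        np.testing.assert_allclose(qr_t, qc)


class TestParallelProject:
    def test_identity_projection(self, rng):
        x = rng.normal(size=(3, 4))
        fc, _ = parallel_project(x, np.eye(4), np.eye(4))
        np.testing.assert_allclose(fc, x)

    def test_uniform_projection_averages_rows(self, rng):
        x = rng.normal(size=(3, 4))
        u = np.full((4, 4), 0.25)
        fc, _ = parallel_project(x, u, u)
        np.testing.assert_allclose(fc, np.tile(x.mean(axis=1)[:, None], 4))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_loop_product(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(3, 4))
        q = np.abs(rng.normal(size=(4, 4)))
        q /= q.sum(axis=0, keepdims=True)
        fc, fr = parallel_project(x, q, q)
        slow = np.zeros((3, 4))
        for i in range(3):
            for j in range(4):
                slow[i, j] = sum(x[i, k] * q[k, j] for k in range(4))
        np.testing.assert_allclose(fc, slow, atol=1e-6)
        np.testing.assert_allclose(fr, slow, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            parallel_project(rng.normal(size=(3, 4)), np.eye(3), np.eye(3))


class TestGating:
    def test_closed_gate(self, rng):
        f = rng.normal(size=(2, 3, 2, 2))
        out = gated_features(f, np.zeros(3), -1.0)
        assert np.abs(out).max() == 0

    def test_unit_gate_passes_through(self, rng):
        f = rng.normal(size=(2, 3, 2, 2))
        np.testing.assert_allclose(gated_features(f, np.zeros(3), 1.0), f)

    def test_scalar_hand_arithmetic(self):
        assert gated_features(np.array(2.0), np.array(1.0), 0.0) == 4.0


class TestCrossEntropy:
    def test_uniform_predictions_ln6(self):
        p = np.full((10, 6), 1 / 6)
        labels = np.arange(10) % 6
        assert cross_entropy_loss(p, labels) == pytest.approx(np.log(6), rel=1e-12)

    def test_perfect_predictions_zero(self):
        p = np.eye(6)
        assert cross_entropy_loss(p, np.arange(6)) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_class_weights(self, rng):
        p = rng.dirichlet(np.ones(6), size=8)
        labels = rng.integers(0, 6, 8)
        base = cross_entropy_loss(p, labels)
        doubled = cross_entropy_loss(p, labels, class_weights=2 * np.ones(6))
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_zero_probability_clamped_with_warning(self):
        p = np.zeros((1, 6))
        p[0, 1] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            loss = cross_entropy_loss(p, np.array([0]))
        assert loss == pytest.approx(-np.log(1e-12))

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.normal(size=(7, 6))
        labels = rng.integers(0, 6, 7)
        with ag.no_grad():
            stable = float(cross_entropy_from_logits(Tensor(logits), labels).data)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        assert stable == pytest.approx(cross_entropy_loss(probs, labels), rel=1e-9)


class TestHeadAndLayer:
    def test_probabilities_sum_to_one(self, rng):
        head = ClassifierHead(8, rng=np.random.default_rng(0), dtype=np.float64)
        x = Tensor(rng.normal(size=(5, 8, 3, 4)))
        with ag.no_grad():
            p = ag.softmax(head(x), axis=1).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p > 0).all() and (p < 1).all()

    def test_zero_weights_give_uniform(self, rng):
        head = ClassifierHead(8, dtype=np.float64)
        head.fc.weight.data[:] = 0
        head.fc.bias.data[:] = 0
        with ag.no_grad():
            p = ag.softmax(head(Tensor(rng.normal(size=(3, 8, 2, 2)))), axis=1).data
        np.testing.assert_allclose(p, 1 / 6, atol=1e-12)

    def test_gap_of_constant_map(self):
        head = ClassifierHead(4, dtype=np.float64)
        x = Tensor(np.full((1, 4, 3, 5), 2.5))
        pooled = ag.mean(x, axis=(2, 3))
        np.testing.assert_allclose(pooled.data, 2.5)

    def test_tspfe_doubles_channels_and_zero_passthrough(self):
        layer = TSPFE(4, 3, rng=np.random.default_rng(0), dtype=np.float64)
        layer.gate_c_b.data = np.array(-1.0)
        layer.gate_r_b.data = np.array(-1.0)
        with ag.no_grad():
            y = layer(Tensor(np.zeros((2, 4, 3, 5))))
        assert y.shape == (2, 8, 3, 5)
        assert np.abs(y.data).max() == 0   # closed gates on zero input

    def test_variant_passthrough_without_tspfe(self):
        cfg = desk_config(8, 32, tdfe_widths=(2, 3, 4), sdfe_width=6, w_max=8,
                          use_tspfe=False)
        model = TSPNet(cfg)
        x = np.random.default_rng(0).normal(size=(2, 8, 32))
        fm = model.feature_maps(x, tap="tspfe")
        assert fm.values.shape[1] == 6     # channels not doubled

    def test_orthogonality_survives_gradient_steps(self, rng):
        layer = TSPFE(3, 4, rng=np.random.default_rng(1), dtype=np.float64)
        x = Tensor(rng.normal(size=(2, 3, 4, 5)))
        for _ in range(5):
            layer.zero_grad()
            out = layer(x)
            ag.sum_(ag.mul(out, out)).backward()
            for p in layer.parameters():
                if p.grad is not None:
                    p.data -= 0.05 * p.grad
        p_mat = layer.orthogonal()
        assert np.abs(p_mat.T @ p_mat - np.eye(4)).max() < 1e-5

    def test_eval_mode_bit_for_bit_deterministic(self, small_epochs):
        cfg = desk_config(16, 128, tdfe_widths=(2, 3, 4), sdfe_width=6, w_max=16)
        model = TSPNet(cfg)
        a = model.predict_proba(small_epochs.data[:4])
        b = model.predict_proba(small_epochs.data[:4])
        np.testing.assert_array_equal(a, b)
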