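"""Forward-pass contracts of the model components and the clustering algebra."""

import numpy as np
import pytest

from pgdas.autodiff import Tensor
from pgdas.model import (PGDASModel, TrainConfig, init_centroids,
                         kl_divergence, soft_assign, target_distribution,
                         total_loss)


def make_model(n_features=20, rng=None, **kw):
    cfg = TrainConfig(ae_hidden=(16, 8), embed_dim=4, **kw)
    return PGDASModel(n_features, cfg, rng or np.random.default_rng(0)), cfg


class TestAutoencoder:
    def test_output_shapes(self, rng):
        model, cfg = make_model()
        X = Tensor(rng.normal(size=(7, 20)))
        z, x_hat = model.ae_forward(X)
        assert z.shape == (7, cfg.embed_dim)
        assert x_hat.shape == (7, 20)

    def test_zero_final_decoder_layer_gives_zero_reconstruction(self, rng):
        model, _ = make_model()
        W, b = model.ae_dec[-1]
        W.value[:] = 0.0
        b.value[:] = 0.0
        _, x_hat = model.ae_forward(Tensor(rng.normal(size=(5, 20))))
        np.testing.assert_array_equal(x_hat.value, 0.0)

    def test_eval_mode_deterministic_despite_dropout(self, rng):
        model, _ = make_model(dropout=0.5)
        X = Tensor(rng.normal(size=(6, 20)))
        z1, _ = model.ae_forward(X, training=False)
        z2, _ = model.ae_forward(X, training=False)
        np.testing.assert_array_equal(z1.value, z2.value)

    def test_hidden_widths_shrink_to_feature_count(self):
        cfg = TrainConfig(ae_hidden=(512, 256), embed_dim=4)
        model = PGDASModel(10, cfg, np.random.default_rng(0))
        assert model.widths == (10, 10, 10, 4)


class TestGraphAutoencoder:
    def test_zero_params_give_half_adjacency(self, rng):
        model, _ = make_model()
        for W, b in model.gae:
            W.value[:] = 0.0
            b.value[:] = 0.0
        A = Tensor(np.eye(5))
        _, w_hat = model.gae_forward(Tensor(rng.normal(size=(5, 20))), A)
        np.testing.assert_allclose(w_hat.value, 0.5)

    def test_reconstruction_symmetric_in_open_interval(self, rng):
        model, _ = make_model()
        A = Tensor(np.eye(6))
        _, w_hat = model.gae_forward(Tensor(rng.normal(size=(6, 20))), A)
        np.testing.assert_allclose(w_hat.value, w_hat.value.T, atol=1e-12)
        # sigmoid range; extreme logits may saturate to the bounds in float64
        assert np.all((w_hat.value >= 0) & (w_hat.value <= 1))

    def test_shape_mismatch_rejected(self, rng):
        model, _ = make_model()
        with pytest.raises(ValueError, match="S x S"):
            model.gae_forward(Tensor(rng.normal(size=(5, 20))),
                              Tensor(np.eye(4)))


class TestFusion:
    def test_zero_gate_logits_average(self, rng):
        model, _ = make_model()
        zg = Tensor(rng.normal(size=(5, 4)))
        za = Tensor(rng.normal(size=(5, 4)))
        zi = model.fuse(zg, za)
        np.testing.assert_allclose(zi.value, (zg.value + za.value) / 2, atol=1e-12)

    def test_saturated_gate_selects_graph_branch(self, rng):
        model, _ = make_model()
        model.gate.value[:] = 50.0
        zg = Tensor(rng.normal(size=(5, 4)))
        za = Tensor(rng.normal(size=(5, 4)))
        np.testing.assert_allclose(model.fuse(zg, za).value, zg.value, atol=1e-10)

    def test_fixed_gate_hand_computation(self):
        model, _ = make_model()
        g = np.array([0.25, 0.75, 0.5, 1.0])
        with np.errstate(divide="ignore"):
            model.gate.value[:] = np.log(g / (1 - g))  # logit
        model.gate.value[3] = 500.0  # saturate where g=1
        zg = Tensor(np.ones((2, 4)))
        za = Tensor(np.zeros((2, 4)))
        np.testing.assert_allclose(model.fuse(zg, za).value,
                                   np.tile(g, (2, 1)), atol=1e-10)

    def test_shape_mismatch(self, rng):
        model, _ = make_model()
        with pytest.raises(ValueError, match="identical shapes"):
            model.fuse(Tensor(np.zeros((2, 4))), Tensor(np.zeros((3, 4))))


class TestAttention:
    def test_zero_value_projection_is_identity(self, rng):
        model, _ = make_model()  # attn_v initialized at zero
        zi = Tensor(rng.normal(size=(6, 4)))
        np.testing.assert_array_equal(model.attention_refine(zi).value, zi.value)

    def test_single_sample(self, rng):
        model, _ = make_model()
        model.attn_v.value[:] = rng.normal(size=(4, 4))
        z = rng.normal(size=(1, 4))
        out = model.attention_refine(Tensor(z))
        np.testing.assert_allclose(out.value, z + z @ model.attn_v.value,
                                   atol=1e-12)

    def test_matches_direct_softmax_recomputation(self, rng):
        model, _ = make_model()
        for p in (model.attn_q, model.attn_k, model.attn_v):
            p.value[:] = rng.normal(size=(4, 4))
        Z = rng.normal(size=(3, 4))
        out = model.attention_refine(Tensor(Z)).value
        scores = (Z @ model.attn_q.value) @ (Z @ model.attn_k.value).T / 2.0
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out, Z + A @ (Z @ model.attn_v.value),
                                   atol=1e-12)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


class TestSoftAssign:
    def test_equidistant_point_splits_evenly(self):
        Z = np.array([[0.0, 0.0]])
        mu = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assign(Z, mu), [[0.5, 0.5]])

    def test_alpha_one_closed_form(self):
        Z = np.array([[0.0]])
        mu = np.array([[0.0], [1.0]])  # squared distances 0 and 1
        np.testing.assert_allclose(soft_assign(Z, mu, alpha=1.0),
                                   [[2 / 3, 1 / 3]], atol=1e-12)

    def test_monotone_in_distance(self, rng):
        Z = rng.normal(size=(1, 3))
        mu = rng.normal(size=(4, 3))
        q = soft_assign(Z, mu)[0]
        closer = mu.copy()
        closer[2] = Z[0] + 0.01 * (mu[2] - Z[0])  # move centroid 2 closer
        q2 = soft_assign(Z, closer)[0]
        assert q2[2] > q[2]

    def test_rows_stochastic(self, rng):
        Q = soft_assign(rng.normal(size=(20, 5)), rng.normal(size=(3, 5)))
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(Q > 0)


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        Q = np.eye(3)[[0, 1, 2, 0]]
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-9)

    def test_uniform_fixed_point(self):
        Q = np.full((5, 3), 1 / 3)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_matches_scalar_oracle(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4]])
        P = target_distribution(Q)
        # independent elementwise evaluation
        f = [0.8 + 0.6, 0.2 + 0.4]
        for i in range(2):
            unnorm = [Q[i, j] ** 2 / f[j] for j in range(2)]
            s = sum(unnorm)
            for j in range(2):
                assert P[i, j] == pytest.approx(unnorm[j] / s, abs=1e-12)
        np.testing.assert_allclose(P[0], [0.8727, 0.1273], atol=1e-4)

    def test_sharpens_rows(self, rng):
        Q = rng.dirichlet(np.ones(4), size=30)
        P = target_distribution(Q)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        # with roughly balanced clusters, sharpening raises the row maximum
        assert (P.max(axis=1) >= Q.max(axis=1) - 0.05).all()

    def test_empty_cluster_rejected(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="empty cluster"):
            target_distribution(Q)


class TestLosses:
    def test_kl_nonnegative_zero_iff_equal(self, rng):
        P = rng.dirichlet(np.ones(3), size=10)
        Q = rng.dirichlet(np.ones(3), size=10)
        assert kl_divergence(P, Q) > 0
        assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_everything_gives_zero(self, rng):
        X = rng.normal(size=(4, 6))
        W = np.array([[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]],
                     dtype=float)
        Q = rng.dirichlet(np.ones(2), size=4)
        assert total_loss(X, X, W, (W > 0).astype(float), Q, Q) == pytest.approx(
            0.0, abs=1e-8)

    def test_gamma_zero_removes_distribution_term(self, rng):
        X = rng.normal(size=(4, 6))
        Xh = rng.normal(size=(4, 6))
        W = np.abs(rng.normal(size=(4, 4)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        Wh = rng.uniform(0.1, 0.9, size=(4, 4))
        Q1 = rng.dirichlet(np.ones(2), size=4)
        Q2 = rng.dirichlet(np.ones(2), size=4)
        P = rng.dirichlet(np.ones(2), size=4)
        l1 = total_loss(X, Xh, W, Wh, Q1, P, gamma=0.0)
        l2 = total_loss(X, Xh, W, Wh, Q2, P, gamma=0.0)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        X = rng.normal(size=(3, 5))
        Xh = rng.normal(size=(3, 5))
        W = np.abs(rng.normal(size=(3, 3)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        Wh = rng.uniform(0.05, 0.95, size=(3, 3))
        Q = rng.dirichlet(np.ones(2), size=3)
        P = rng.dirichlet(np.ones(2), size=3)
        beta, gamma = 0.7, 0.3

        mse = sum((X[i, j] - Xh[i, j]) ** 2 for i in range(3) for j in range(5)) / 15
        B = (W > 0).astype(float)
        pw = (B.size - B.sum()) / B.sum()
        bce = -sum(pw * B[i, j] * np.log(Wh[i, j])
                   + (1 - B[i, j]) * np.log(1 - Wh[i, j])
                   for i in range(3) for j in range(3)) / 9
        kl = sum(P[i, j] * np.log(P[i, j] / Q[i, j])
                 for i in range(3) for j in range(2)) / 3
        expected = mse + beta * bce + gamma * kl
        assert total_loss(X, Xh, W, Wh, Q, P, beta, gamma) == pytest.approx(
            expected, abs=1e-8)


class TestInitCentroids:
    def test_k_equals_distinct_rows(self, rng):
        Z = rng.normal(size=(5, 3))
        mu, labels = init_centroids(Z, 5, seed=0)
        assert sorted(map(tuple, np.round(mu, 9))) == sorted(
            map(tuple, np.round(Z, 9)))
        inertia = sum(np.min(((Z[i] - mu) ** 2).sum(axis=1)) for i in range(5))
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_two_blob_recovery(self, rng):
        a = rng.normal(loc=0.0, scale=0.2, size=(50, 2))
        b = rng.normal(loc=5.0, scale=0.2, size=(50, 2))
        Z = np.vstack([a, b])
        mu, _ = init_centroids(Z, 2, seed=1)
        mu = mu[np.argsort(mu[:, 0])]
        sem = 0.2 / np.sqrt(50)
        assert np.all(np.abs(mu[0] - a.mean(axis=0)) < 3 * sem)
        assert np.all(np.abs(mu[1] - b.mean(axis=0)) < 3 * sem)

    def test_deterministic_given_seed(self, rng):
        Z = rng.normal(size=(30, 4))
        mu1, l1 = init_centroids(Z, 3, seed=9)
        mu2, l2 = init_centroids(Z, 3, seed=9)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(l1, l2)

    def test_k_exceeding_distinct_rows_rejected(self):
        Z = np.tile([[1.0, 2.0]], (6, 1))
        with pytest.raises(ValueError, match="distinct"):
            init_centroids(Z, 2, seed=0)
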