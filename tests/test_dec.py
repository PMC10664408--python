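"""DEC core: pretraining, soft assignment, target distribution, self-training."""
import numpy as np
import pytest

from gdec import (
    DecFitConfig,
    EncoderSpec,
    PretrainConfig,
    SimulationConfig,
    SoftAssignment,
    dec_fit,
    encode,
    hungarian_accuracy,
    init_centroids,
    kl_loss,
    normalize,
    pretrain_autoencoder,
    simulate_expression,
    soft_assign,
    target_distribution,
    ari,
)
from gdec.dec import _build_networks


def two_loop_soft_assign(Z, mu, alpha):
    """Independent straightforward implementation of the Student's-t rows."""
    n, k = Z.shape[0], mu.shape[0]
    q = np.zeros((n, k))
    for i in range(n):
        for j in range(k):
            d2 = float(((Z[i] - mu[j]) ** 2).sum())
            q[i, j] = (1 + d2 / alpha) ** (-(alpha + 1) / 2)
        q[i] /= q[i].sum()
    return q


class TestPretrainAutoencoder:
    def test_epochs_zero_is_seeded_random_init(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10)) ** 2
        spec = EncoderSpec(10, (8, 8, 12), 4)
        st = pretrain_autoencoder(X, spec, PretrainConfig(epochs=0, seed=5))
        enc_ref, dec_ref = _build_networks(spec, 5)
        recon = st.decoder.forward(st.encoder.forward(X))
        ref = dec_ref.forward(enc_ref.forward(X))
        assert np.array_equal(recon, ref)

    def test_training_reduces_reconstruction_error(self):
        cfg = SimulationConfig(n_cells=300, n_genes=50, k_types=3,
                               markers_per_type=8, seed=2)
        X = normalize(simulate_expression(cfg)[0]).values
        spec = EncoderSpec(50, (32, 32, 64), 20)
        st = pretrain_autoencoder(X, spec, PretrainConfig(epochs=100, seed=3))
        assert st.pretrain_loss[-1] < st.pretrain_loss[0]

    def test_duplicate_columns_reconstruct_alike(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(300, 19)) ** 2
        X = np.hstack([base, base[:, [0]]])  # column 19 duplicates column 0
        spec = EncoderSpec(20, (16, 16, 32), 8)
        st = pretrain_autoencoder(X, spec, PretrainConfig(epochs=100, seed=4))
        recon = st.decoder.forward(st.encoder.forward(X))
        overall = float(np.sqrt(((recon - X) ** 2).mean()))
        dup_gap = float(np.abs(recon[:, 0] - recon[:, 19]).mean())
        assert dup_gap <= 10 * overall

    def test_nonfinite_input_rejected(self):
        spec = EncoderSpec(2, (2,), 2)
        with pytest.raises(ValueError, match="non-finite"):
            pretrain_autoencoder(np.array([[1.0, np.nan]]), spec)


class TestEncode:
    def _state(self, width=6):
        return pretrain_autoencoder(
            np.random.default_rng(0).normal(size=(10, width)),
            EncoderSpec(width, (4,), 3),
            PretrainConfig(epochs=0, seed=1),
        )

    def test_identical_rows_identical_embeddings(self):
        st = self._state()
        X = np.tile([[1.0, 2, 3, 4, 5, 6]], (3, 1))
        Z = encode(st, X)
        assert np.array_equal(Z[0], Z[1]) and np.array_equal(Z[1], Z[2])

    def test_zero_weights_zero_embeddings(self):
        st = self._state()
        for layer in st.encoder.layers:
            layer.W[:] = 0
            layer.b[:] = 0
        assert np.array_equal(encode(st, np.ones((2, 6))), np.zeros((2, 3)))

    def test_single_row_matches_batch_row(self):
        st = self._state()
        X = np.random.default_rng(2).normal(size=(5, 6))
        assert np.allclose(encode(st, X[[3]]), encode(st, X)[3])

    def test_width_mismatch(self):
        st = self._state()
        with pytest.raises(ValueError, match="input width"):
            encode(st, np.ones((2, 7)))


class TestInitCentroids:
    def test_k1_is_mean(self):
        Z = np.random.default_rng(0).normal(size=(30, 5))
        mu = init_centroids(Z, 1, seed=0)
        assert np.allclose(mu[0], Z.mean(axis=0), atol=1e-9)

    def test_two_point_masses(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1e-8, size=(20, 3)) + 5.0
        b = rng.normal(0, 1e-8, size=(20, 3)) - 5.0
        mu = init_centroids(np.vstack([a, b]), 2, seed=0)
        mu = mu[np.argsort(mu[:, 0])]
        assert np.allclose(mu[0], b.mean(axis=0), atol=1e-6)
        assert np.allclose(mu[1], a.mean(axis=0), atol=1e-6)

    def test_determinism(self):
        Z = np.random.default_rng(2).normal(size=(50, 4))
        assert np.array_equal(init_centroids(Z, 3, seed=9), init_centroids(Z, 3, seed=9))

    def test_too_many_clusters(self):
        Z = np.zeros((5, 2))
        with pytest.raises(ValueError, match="distinct"):
            init_centroids(Z, 2, seed=0)


class TestSoftAssign:
    def test_kernel_monotone_in_distance(self):
        Z = np.array([[0.0, 0.0]])
        mu = np.array([[0.0, 0.0], [3.0, 0.0]])
        q = soft_assign(Z, mu).Q
        assert q[0, 0] > q[0, 1]

    def test_equidistant_gives_half(self):
        Z = np.array([[0.0]])
        mu = np.array([[-2.0], [2.0]])
        assert np.allclose(soft_assign(Z, mu).Q, [[0.5, 0.5]])

    def test_hand_computed_alpha1(self):
        q = soft_assign(np.array([[0.0]]), np.array([[0.0], [1.0]]), alpha=1.0).Q
        assert np.allclose(q, [[2 / 3, 1 / 3]], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_two_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(12, 4))
        mu = rng.normal(size=(3, 4))
        alpha = float(rng.uniform(0.5, 3.0))
        assert np.allclose(soft_assign(Z, mu, alpha).Q,
                           two_loop_soft_assign(Z, mu, alpha), atol=1e-8)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        q = soft_assign(rng.normal(size=(40, 6)), rng.normal(size=(5, 6))).Q
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-6)


class TestTargetDistribution:
    def test_single_sample_fixed_point(self):
        q = SoftAssignment(np.array([[0.3, 0.7]]))
        assert np.allclose(target_distribution(q).P, q.Q, atol=1e-12)

    def test_hand_computed_two_rows(self):
        q = SoftAssignment(np.array([[0.9, 0.1], [0.6, 0.4]]))
        td = target_distribution(q)
        assert np.allclose(td.f, [1.5, 0.5])
        assert np.allclose(td.P, [[0.9643, 0.0357], [0.4286, 0.5714]], atol=1e-4)

    def test_uniform_rows_fixed_point(self):
        q = SoftAssignment(np.full((4, 5), 0.2))
        assert np.allclose(target_distribution(q).P, q.Q, atol=1e-12)

    def test_sharpens_confident_rows(self):
        q = SoftAssignment(np.array([[0.7, 0.3], [0.5, 0.5]]))
        p = target_distribution(q).P
        assert p[0, 0] > 0.7


class TestKlLoss:
    def test_zero_iff_equal(self):
        q = np.array([[0.4, 0.6], [0.5, 0.5]])
        assert kl_loss(q, q) == 0.0

    def test_hand_computed(self):
        val = kl_loss(np.array([[0.75, 0.25]]), np.array([[0.5, 0.5]]))
        expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
        assert np.isclose(val, expected, atol=1e-12)
        assert np.isclose(val, 0.13081, atol=1e-5)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.dirichlet(np.ones(4), size=6)
            q = rng.dirichlet(np.ones(4), size=6)
            assert kl_loss(p, q) >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            kl_loss(np.ones((1, 2)) / 2, np.ones((2, 2)) / 2)


class TestDecFit:
    def _fitted_state(self, X, k, seed, hidden=(32, 32, 64), epochs=120):
        spec = EncoderSpec(X.shape[1], hidden, 20)
        st = pretrain_autoencoder(X, spec, PretrainConfig(epochs=epochs, seed=seed))
        st.centroids = init_centroids(encode(st, X), k, seed=seed)
        return st

    def test_max_iters_zero_is_noop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10)) ** 2
        st = self._fitted_state(X, 3, 0)
        w_before = [p.copy() for p in st.encoder.params()]
        out, Q = dec_fit(st, X, DecFitConfig(max_iters=0))
        assert all(np.array_equal(a, b) for a, b in zip(w_before, out.encoder.params()))
        assert np.allclose(Q.Q, soft_assign(encode(st, X), st.centroids, st.alpha).Q)

    def test_uninitialised_centroids_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 8)) ** 2
        spec = EncoderSpec(8, (4,), 3)
        st = pretrain_autoencoder(X, spec, PretrainConfig(epochs=0))
        with pytest.raises(RuntimeError, match="centroids"):
            dec_fit(st, X)

    def test_recovers_planted_clusters(self):
        """Well-separated synthetic clusters are recovered nearly perfectly."""
        accs, aris = [], []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(n_cells=300, n_genes=60, k_types=3,
                                   markers_per_type=10, separation=4.0,
                                   dropout_rate=0.2, seed=seed)
            expr, labels = simulate_expression(cfg)
            X = normalize(expr).values
            st = self._fitted_state(X, 3, seed, hidden=(128, 128, 512), epochs=200)
            st, Q = dec_fit(st, X, DecFitConfig(max_iters=120, seed=seed))
            accs.append(hungarian_accuracy(labels, Q.hard()))
            aris.append(ari(labels, Q.hard()))
            # row-sum invariant holds on the final assignment
            assert np.allclose(Q.Q.sum(axis=1), 1.0, atol=1e-6)
        assert min(accs) >= 0.95
        assert min(aris) >= 0.9

    def test_kl_history_mostly_decreasing(self):
        cfg = SimulationConfig(n_cells=300, n_genes=60, k_types=3,
                               markers_per_type=10, separation=4.0,
                               dropout_rate=0.2, seed=1)
        expr, _ = simulate_expression(cfg)
        X = normalize(expr).values
        st = self._fitted_state(X, 3, 1, hidden=(128, 128, 512), epochs=200)
        st, _ = dec_fit(st, X, DecFitConfig(max_iters=120, update_interval=20, seed=1))
        h = st.kl_history
        drops = sum(1 for a, b in zip(h, h[1:]) if b <= a + 1e-9)
        assert drops >= 0.8 * (len(h) - 1)
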