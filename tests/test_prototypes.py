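"""Prototype machinery: k-means, EMA algebra, dynamic temperatures, loss oracle."""

import numpy as np
import pytest

from wearssl.data import ValidationError
from wearssl.losses import EmbeddingBatch
from wearssl.prototypes import (PrototypeBank, ema_update, kmeans_assign,
                                prototype_loss, prototype_loss_and_grad,
                                raw_cluster_temperature, update_temperatures)
from conftest import random_embedding_batch


def _bank(K, dim, assignments, c=None, tau=None, **kw):
    b = PrototypeBank(K=K, dim=dim, assignments=np.asarray(assignments), **kw)
    if c is not None:
        b.c = np.asarray(c, dtype=float)
    if tau is not None:
        b.tau_k = np.asarray(tau, dtype=float)
    return b


def oracle_prototype_loss(z, ks, c, tau_k):
    total = 0.0
    for i in range(len(z)):
        num = np.exp(z[i] @ c[ks[i]] / tau_k[ks[i]])
        den = sum(np.exp(z[i] @ c[j] / tau_k[j]) for j in range(len(c)))
        total += -np.log(num / den)
    return total / len(z)


class TestKMeans:
    def test_two_separated_blobs_pure(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(10, 0.1, (50, 2))])
        labels, _ = kmeans_assign(X, K=2, seed=1)
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_k1_gives_global_mean(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        labels, centroids = kmeans_assign(X, K=1, seed=0)
        assert np.all(labels == 0)
        assert centroids[0, 0] == pytest.approx(4.5)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(1).standard_normal((40, 3))
        a1, _ = kmeans_assign(X, K=5, seed=7)
        a2, _ = kmeans_assign(X, K=5, seed=7)
        assert np.array_equal(a1, a2)

    def test_nan_rejected_and_k_reduced(self):
        with pytest.raises(ValidationError):
            kmeans_assign(np.array([[np.nan]]), K=1)
        with pytest.warns(UserWarning):
            labels, _ = kmeans_assign(np.random.default_rng(0).standard_normal((3, 2)), K=5)
        assert labels.max() < 3


class TestEMA:
    def _batch(self, z_rows):
        z = np.asarray(z_rows, dtype=float)
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        n = len(z) // 2
        return EmbeddingBatch(z=z, view_to_source=np.repeat(np.arange(n), 2),
                              d=np.zeros((len(z), 1)))

    def test_alpha_one_keeps_prototypes(self):
        b = self._batch([[1, 0], [0, 1]])
        bank = _bank(1, 2, [0], c=[[0.6, 0.8]], alpha=1.0)
        ema_update(bank, b)
        assert np.allclose(bank.c, [[0.6, 0.8]])

    def test_alpha_zero_takes_batch_mean(self):
        b = self._batch([[1, 0], [1, 0]])
        bank = _bank(1, 2, [0], c=[[0.0, 1.0]], alpha=0.0)
        ema_update(bank, b)
        assert np.allclose(bank.c, [[1.0, 0.0]], atol=1e-12)

    def test_half_half_then_renormalized(self):
        """alpha=0.5, c=[1,0], member mean [0,1] -> [0.5,0.5] -> unit [0.7071,0.7071]."""
        b = self._batch([[0, 1], [0, 1]])
        bank = _bank(1, 2, [0], c=[[1.0, 0.0]], alpha=0.5)
        ema_update(bank, b)
        assert np.allclose(bank.c, [[np.sqrt(0.5), np.sqrt(0.5)]], atol=1e-9)

    def test_fixed_point_when_batch_mean_equals_prototype(self):
        c = np.array([[0.6, 0.8]])
        b = self._batch([[0.6, 0.8], [0.6, 0.8]])
        for alpha in (0.0, 0.3, 1.0):
            bank = _bank(1, 2, [0], c=c.copy(), alpha=alpha)
            ema_update(bank, b)
            assert np.allclose(bank.c, c, atol=1e-12)

    def test_absent_cluster_unchanged_and_alpha_validated(self):
        b = self._batch([[1, 0], [1, 0]])
        bank = _bank(2, 2, [0, 0, 1], c=[[1, 0], [0, 1]], alpha=0.5)
        ema_update(bank, b)
        assert np.allclose(bank.c[1], [0, 1])
        with pytest.raises(ValidationError):
            PrototypeBank(K=1, dim=2, alpha=1.5)


class TestTemperatures:
    def test_raw_value_hand_computed(self):
        """Single member at distance 0.5, m=10: raw tau = 0.5/ln(11) = 0.20852."""
        assert raw_cluster_temperature(0.5, 1, 10) == pytest.approx(0.5 / np.log(11), abs=1e-12)
        assert raw_cluster_temperature(0.5, 1, 10) == pytest.approx(0.20852, abs=1e-5)

    def test_identical_raw_values_normalize_to_base(self):
        bank = _bank(2, 2, [0, 1], c=np.eye(2), base_tau=0.2)
        bank.dist_sum = np.array([0.3, 0.3])
        bank.n_k = np.array([2, 2])
        update_temperatures(bank)
        assert np.allclose(bank.tau_k, [0.2, 0.2])

    def test_rescaling_preserves_ratios_and_mean(self):
        """Raw {0.2, 0.6} at base 0.2 -> {0.1, 0.3}."""
        bank = _bank(2, 2, [0, 1], c=np.eye(2), base_tau=0.2, m=10)
        # choose dist sums that give raw tau exactly 0.2 and 0.6 with n_k=1
        bank.dist_sum = np.array([0.2 * np.log(11), 0.6 * np.log(11)])
        bank.n_k = np.array([1, 1])
        update_temperatures(bank)
        assert np.allclose(bank.tau_k, [0.1, 0.3], atol=1e-12)
        assert bank.tau_k.mean() == pytest.approx(0.2, abs=1e-9)

    def test_normalization_idempotent(self):
        bank = _bank(3, 2, [0, 1, 2], c=np.eye(3)[:, :2], base_tau=0.1)
        bank.dist_sum = np.array([0.5, 0.2, 0.9])
        bank.n_k = np.array([3, 1, 2])
        update_temperatures(bank)
        tau1 = bank.tau_k.copy()
        bank.tau_k = tau1 * (bank.base_tau / tau1.mean())   # renormalize again
        assert np.allclose(bank.tau_k, tau1)

    def test_empty_epoch_warns_and_keeps_taus(self):
        bank = _bank(2, 2, [0, 1], c=np.eye(2), base_tau=0.1)
        before = bank.tau_k.copy()
        with pytest.warns(UserWarning):
            update_temperatures(bank)
        assert np.array_equal(bank.tau_k, before)

    def test_unseen_cluster_retains_previous_tau(self):
        bank = _bank(2, 2, [0, 1], c=np.eye(2), base_tau=0.2)
        bank.tau_k = np.array([0.5, 0.1])
        bank.dist_sum = np.array([0.4, 0.0])
        bank.n_k = np.array([2, 0])
        update_temperatures(bank)
        # cluster 1 kept raw value 0.1 before the common rescale
        raw0 = raw_cluster_temperature(0.4, 2, 10)
        expect = np.array([raw0, 0.1])
        expect *= 0.2 / expect.mean()
        assert np.allclose(bank.tau_k, expect)


class TestPrototypeLoss:
    def test_single_cluster_is_zero(self):
        rng = np.random.default_rng(0)
        b = random_embedding_batch(rng, n_sources=3, dim=4)
        bank = _bank(1, 4, [0, 0, 0], c=[[1, 0, 0, 0]])
        assert prototype_loss(b, bank) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_prototypes(self):
        """z = c_1 = [1,0], c_2 = [0,1], unit temperatures: -ln(e/(e+1))."""
        z = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = EmbeddingBatch(z=z, view_to_source=np.array([0, 0]), d=np.zeros((2, 1)))
        bank = _bank(2, 2, [0], c=[[1.0, 0.0], [0.0, 1.0]], tau=[1.0, 1.0])
        assert prototype_loss(b, bank) == pytest.approx(0.313262, abs=1e-6)

    def test_identical_prototypes_give_lnK(self):
        rng = np.random.default_rng(1)
        b = random_embedding_batch(rng, n_sources=4, dim=3)
        K = 5
        bank = _bank(K, 3, rng.integers(0, K, 4), c=np.tile([1.0, 0, 0], (K, 1)),
                     tau=np.full(K, 0.2))
        assert prototype_loss(b, bank) == pytest.approx(np.log(K), abs=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            K = int(rng.integers(1, 8))
            n = int(rng.integers(2, 8))
            b = random_embedding_batch(rng, n_sources=n, dim=4)
            c = rng.standard_normal((K, 4))
            c /= np.linalg.norm(c, axis=1, keepdims=True)
            tau = rng.uniform(0.05, 0.5, K)
            bank = _bank(K, 4, rng.integers(0, K, n), c=c, tau=tau)
            ks = bank.view_clusters(b)
            assert prototype_loss(b, bank) == pytest.approx(
                oracle_prototype_loss(b.z, ks, c, tau), abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        b = random_embedding_batch(rng, n_sources=3, dim=3)
        c = rng.standard_normal((4, 3))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        bank = _bank(4, 3, [0, 2, 3], c=c, tau=[0.1, 0.2, 0.15, 0.3])
        L, dz = prototype_loss_and_grad(b, bank)
        for i in (0, 5):
            for j in range(3):
                z2 = b.z.copy()
                z2[i, j] += 1e-7
                b2 = EmbeddingBatch.__new__(EmbeddingBatch)
                b2.z, b2.view_to_source, b2.d = z2, b.view_to_source, b.d
                L2, _ = prototype_loss_and_grad(b2, bank, need_grad=False)
                assert (L2 - L) / 1e-7 == pytest.approx(dz[i, j], abs=1e-4)

    def test_uninitialized_bank_rejected(self):
        rng = np.random.default_rng(4)
        b = random_embedding_batch(rng, n_sources=2, dim=3)
        with pytest.raises(ValidationError):
            prototype_loss(b, _bank(2, 3, [0, 1]))
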