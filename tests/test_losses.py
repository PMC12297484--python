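"""Instance-level losses against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wearssl.data import ValidationError
from wearssl.losses import (EmbeddingBatch, build_pair_assignment, info_nce,
                            instance_loss, instance_loss_and_grad,
                            select_domain_neighbors)
from conftest import random_embedding_batch


def oracle_instance_loss(z, pairs, tau):
    """Naive double-loop evaluation of the multi-positive loss."""
    total = 0.0
    for i in range(len(z)):
        P, N = pairs.positives[i], pairs.negatives[i]
        acc = 0.0
        for p in P:
            num = np.exp(z[i] @ z[p] / tau)
            den = num + sum(np.exp(z[i] @ z[n] / tau) for n in N)
            acc += -np.log(num / den)
        total += acc / len(P)
    return total / len(z)


def oracle_one_positive_batch(z, pairs, tau):
    """Plain InfoNCE batch loss: one positive (the sibling), rest negatives."""
    total = 0.0
    for i in range(len(z)):
        p = pairs.sibling[i]
        negs = [j for j in range(len(z)) if j not in (i, p)]
        total += info_nce(z[i], z[p], z[negs], tau)
    return total / len(z)


class TestInfoNCE:
    def test_identical_pair_no_negatives_is_zero(self):
        z = np.array([1.0, 0.0])
        assert info_nce(z, z, np.zeros((0, 2)), tau=1.0) == pytest.approx(0.0)

    def test_aligned_pair_one_orthogonal_negative(self):
        """-ln(e/(e+1)) = 0.31326."""
        zi = np.array([1.0, 0.0])
        zn = np.array([[0.0, 1.0]])
        assert info_nce(zi, zi, zn, tau=1.0) == pytest.approx(0.313262, abs=1e-6)

    def test_symmetric_half_half_is_ln2(self):
        zi = np.array([1.0, 0.0])
        zp = np.array([0.0, 1.0])
        zn = np.array([[0.0, -1.0]])
        assert info_nce(zi, zp, zn, tau=1.0) == pytest.approx(np.log(2), abs=1e-9)

    def test_invalid_temperature(self):
        z = np.array([1.0, 0.0])
        with pytest.raises(ValidationError):
            info_nce(z, z, np.zeros((0, 2)), tau=0.0)


class TestNeighborSelection:
    def _batch_with_d(self, d_sources):
        n = len(d_sources)
        z = np.tile(np.eye(max(n * 2, 2))[: 2 * n, : 3], 1)
        z = np.random.default_rng(0).standard_normal((2 * n, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        d = np.repeat(np.asarray(d_sources, dtype=float), 2, axis=0)
        return EmbeddingBatch(z=z, view_to_source=np.repeat(np.arange(n), 2), d=d)

    def test_distance_table_example(self):
        """Sources at [0,0],[3,0],[0.5,0],[10,10]: nearest to 0 is source 2."""
        b = self._batch_with_d([[0, 0], [3, 0], [0.5, 0], [10, 10]])
        S = select_domain_neighbors(0, b, count=2)
        assert sorted(S) == [4, 5]               # both views of source 2

    def test_tie_break_by_ascending_view_index(self):
        b = self._batch_with_d([[1, 1]] * 4)
        S = select_domain_neighbors(0, b, count=2)
        assert S == [2, 3]                        # lowest-indexed non-sibling views

    def test_two_source_batch_returns_other_source(self):
        b = self._batch_with_d([[0, 0], [5, 5]])
        S = select_domain_neighbors(0, b, count=2)
        assert sorted(S) == [2, 3]

    def test_single_source_rejected(self):
        z = np.random.default_rng(0).standard_normal((2, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        b = EmbeddingBatch(z=z, view_to_source=np.array([0, 0]), d=np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            select_domain_neighbors(0, b, count=2)


class TestInstanceLoss:
    def test_reduces_to_plain_infonce_without_neighbors(self):
        """With P(i) = {sibling} only, the loss equals the one-positive batch
        loss to machine precision."""
        rng = np.random.default_rng(0)
        b = random_embedding_batch(rng, n_sources=5, dim=4)
        pairs = build_pair_assignment(b, n_neighbors=0)
        L = instance_loss(b, pairs, tau=0.5)
        assert L == pytest.approx(oracle_one_positive_batch(b.z, pairs, 0.5), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b = random_embedding_batch(rng, n_sources=int(rng.integers(2, 8)), dim=3)
            pairs = build_pair_assignment(b, n_neighbors=2)
            L = instance_loss(b, pairs, tau=0.5)
            assert L == pytest.approx(oracle_instance_loss(b.z, pairs, 0.5), abs=1e-6)

    def test_all_identical_embeddings_closed_form(self):
        """All z equal, |P| = 3: per-anchor loss is ln(1 + |N*|), any tau."""
        n_sources = 6
        z = np.tile(np.array([1.0, 0.0, 0.0]), (2 * n_sources, 1))
        d = np.repeat(np.arange(n_sources, dtype=float)[:, None], 2, axis=0)
        b = EmbeddingBatch(z=z, view_to_source=np.repeat(np.arange(n_sources), 2), d=d)
        pairs = build_pair_assignment(b, n_neighbors=2)
        m = len(pairs.negatives[0])
        assert m == 2 * n_sources - 4
        L = instance_loss(b, pairs, tau=0.3)
        assert L == pytest.approx(np.log(1 + m), abs=1e-9)

    def test_neighbors_removed_from_negative_pool(self):
        rng = np.random.default_rng(2)
        b = random_embedding_batch(rng, n_sources=6)
        pairs = build_pair_assignment(b, n_neighbors=2)
        for i in range(b.n_views):
            assert not set(pairs.neighbors[i]) & set(pairs.negatives[i])
            assert i not in pairs.positives[i]
            assert not set(pairs.positives[i]) & set(pairs.negatives[i])
            covered = {i} | set(pairs.positives[i]) | set(pairs.negatives[i])
            assert covered == set(range(b.n_views))

    def test_monotonicity_in_negative_similarity(self):
        """Rotating one negative toward the anchor never decreases the loss."""
        n_sources = 4
        rng = np.random.default_rng(3)
        b = random_embedding_batch(rng, n_sources=n_sources)
        pairs = build_pair_assignment(b, n_neighbors=1)
        neg = pairs.negatives[0][0]
        losses = []
        for t in np.linspace(0, 1, 5):
            z = b.z.copy()
            v = (1 - t) * z[neg] + t * z[0]
            z[neg] = v / np.linalg.norm(v)
            b2 = EmbeddingBatch(z=z, view_to_source=b.view_to_source, d=b.d)
            # keep the same pair structure; only anchor 0's term changes monotonically
            losses.append(
                -np.log(np.exp(z[0] @ z[pairs.sibling[0]] / 0.5) /
                        (np.exp(z[0] @ z[pairs.sibling[0]] / 0.5) +
                         sum(np.exp(z[0] @ z[n] / 0.5) for n in pairs.negatives[0]))))
        assert np.all(np.diff(losses) >= -1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        b = random_embedding_batch(rng, n_sources=4, dim=3)
        pairs = build_pair_assignment(b, n_neighbors=2)
        L, dz = instance_loss_and_grad(b, pairs, tau=0.5)
        for i in (0, 3):
            for j in range(3):
                z2 = b.z.copy()
                z2[i, j] += 1e-7
                b2 = EmbeddingBatch.__new__(EmbeddingBatch)
                b2.z, b2.view_to_source, b2.d = z2, b.view_to_source, b.d
                L2, _ = instance_loss_and_grad(b2, pairs, 0.5, need_grad=False)
                assert (L2 - L) / 1e-7 == pytest.approx(dz[i, j], abs=1e-4)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(n_sources=st.integers(2, 8), n_neighbors=st.integers(0, 2),
       tau=st.floats(0.1, 2.0), seed=st.integers(0, 10_000))
def test_vectorized_loss_equals_oracle_property(n_sources, n_neighbors, tau, seed):
    """Randomized equivalence of the vectorized loss and the naive oracle."""
    rng = np.random.default_rng(seed)
    b = random_embedding_batch(rng, n_sources=n_sources, dim=4)
    k = min(n_neighbors, 2 * n_sources - 2)
    pairs = build_pair_assignment(b, n_neighbors=k)
    assert instance_loss(b, pairs, tau) == pytest.approx(
        oracle_instance_loss(b.z, pairs, tau), abs=1e-6)
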