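"""Prototype-level contrast: offline k-means, EMA updates, dynamic temperatures.

Cluster structure comes from the *domain features*, not from the embeddings:
k-means runs once, offline, on the z-normalized feature matrix, and the
resulting assignments never change during training.  Each cluster k keeps a
prototype c_k in projection space, updated per batch as an exponential
moving average of its members' projections, and a temperature tau_k,
recomputed once per epoch from the members' mean distance to the prototype
so that loosely packed clusters get proportionally softer contrast:

    tau_k = (sum_i ||z_i - c_k||_2) / (n_k * ln(n_k + m)),

then rescaled by one constant so the cluster mean equals the base
temperature.  The prototype loss pulls each view toward its own prototype
against all K prototypes, each term using its own cluster's temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data import ValidationError
from .features import DomainFeatureMatrix
from .losses import EmbeddingBatch

__all__ = [
    "PrototypeBank", "kmeans_assign", "ema_update",
    "raw_cluster_temperature", "update_temperatures",
    "prototype_loss", "prototype_loss_and_grad",
]


def kmeans_assign(features: DomainFeatureMatrix | np.ndarray, K: int,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Offline k-means on domain features; returns (assignments, centroids).

    Greedy spreading (k-means++) initialization, deterministic under seed.
    K is reduced with a warning when there are fewer rows than clusters.
    """
    X = features.values if isinstance(features, DomainFeatureMatrix) else np.asarray(features)
    if not np.isfinite(X).all():
        raise ValidationError("NaN/Inf in features passed to k-means")
    if K < 1:
        raise ValidationError("K must be >= 1")
    if X.shape[0] < K:
        warnings.warn(f"K={K} > {X.shape[0]} samples; reducing K to {X.shape[0]}")
        K = X.shape[0]
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, max_iter=300,
                tol=1e-4, random_state=seed)
    labels = km.fit_predict(X)
    return labels.astype(np.int64), km.cluster_centers_


@dataclass
class PrototypeBank:
    """Prototypes, per-cluster temperatures and epoch-scoped member statistics."""

    K: int
    dim: int
    base_tau: float = 0.1
    alpha: float = 0.5              # EMA momentum
    m: int = 10                     # temperature smoothing count
    normalize_prototypes: bool = True
    assignments: np.ndarray | None = None   # per source segment, values in [0, K)
    c: np.ndarray | None = None             # (K, dim); None until initialized
    tau_k: np.ndarray = None                # (K,)
    # epoch-scoped accumulators for the temperature update
    dist_sum: np.ndarray = None
    n_k: np.ndarray = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1]")
        if self.base_tau <= 0:
            raise ValidationError("base_tau must be > 0")
        if self.tau_k is None:
            self.tau_k = np.full(self.K, self.base_tau)
        if self.dist_sum is None:
            self.dist_sum = np.zeros(self.K)
        if self.n_k is None:
            self.n_k = np.zeros(self.K, dtype=np.int64)

    @property
    def initialized(self) -> bool:
        return self.c is not None

    def reset_epoch_stats(self) -> None:
        self.dist_sum[...] = 0.0
        self.n_k[...] = 0

    def view_clusters(self, batch: EmbeddingBatch) -> np.ndarray:
        if self.assignments is None:
            raise ValidationError("bank has no offline assignments")
        return self.assignments[batch.view_to_source]


def ema_update(bank: PrototypeBank, batch: EmbeddingBatch) -> PrototypeBank:
    """Per-batch EMA of each represented cluster's mean projection (in place).

    c_k' = alpha * c_k + (1 - alpha) * mean of member projections; clusters
    with no members in the batch are unchanged.  Updated prototypes are
    re-normalized to unit norm when ``normalize_prototypes`` (default), so
    z.c stays a cosine similarity.  Member distances to the (updated)
    prototype are accumulated for the end-of-epoch temperature update.
    """
    if not bank.initialized:
        raise ValidationError("prototypes not initialized")
    ks = bank.view_clusters(batch)
    for k in np.unique(ks):
        members = batch.z[ks == k]
        mean = members.mean(axis=0)
        bank.c[k] = bank.alpha * bank.c[k] + (1.0 - bank.alpha) * mean
        if bank.normalize_prototypes:
            nrm = np.linalg.norm(bank.c[k])
            if nrm > 1e-12:
                bank.c[k] /= nrm
        d = np.linalg.norm(members - bank.c[k], axis=1)
        bank.dist_sum[k] += d.sum()
        bank.n_k[k] += len(members)
    return bank


def raw_cluster_temperature(dist_sum: float, n_k: int, m: int) -> float:
    """Un-normalized dynamic temperature (sum of member distances) / (n ln(n+m))."""
    return dist_sum / (n_k * np.log(n_k + m))


def update_temperatures(bank: PrototypeBank) -> PrototypeBank:
    """End-of-epoch temperature refresh from accumulated member distances.

    Clusters unseen this epoch retain their previous temperature; all
    temperatures are then rescaled by one constant so their mean equals
    ``base_tau`` (idempotent: renormalizing changes nothing).
    """
    if bank.n_k.sum() == 0:
        warnings.warn("no cluster received members this epoch; temperatures unchanged")
        return bank
    raw = bank.tau_k.copy()
    seen = bank.n_k >= 1
    raw[seen] = [raw_cluster_temperature(bank.dist_sum[k], int(bank.n_k[k]), bank.m)
                 for k in np.flatnonzero(seen)]
    raw = np.maximum(raw, 1e-12)
    bank.tau_k = raw * (bank.base_tau / raw.mean())
    bank.reset_epoch_stats()
    return bank


def prototype_loss(batch: EmbeddingBatch, bank: PrototypeBank) -> float:
    loss, _ = prototype_loss_and_grad(batch, bank, need_grad=False)
    return loss


def prototype_loss_and_grad(batch: EmbeddingBatch, bank: PrototypeBank,
                            need_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Mean over views of -log exp(z.c_{k_i}/tau_{k_i}) / sum_j exp(z.c_j/tau_j).

    Each denominator term uses its own cluster's temperature.  Prototypes are
    treated as constants (they evolve by EMA, not by gradient); the gradient
    is with respect to z only.
    """
    if bank.K == 0 or not bank.initialized:
        raise ValidationError("bank has no prototypes")
    ks = bank.view_clusters(batch)
    A = batch.z @ (bank.c / bank.tau_k[:, None]).T      # (nV, K)
    m = A.max(axis=1, keepdims=True)
    expA = np.exp(A - m)
    lse = m[:, 0] + np.log(expA.sum(axis=1))
    own = A[np.arange(len(ks)), ks]
    loss = float(np.mean(lse - own))
    if not need_grad:
        return loss, None
    soft = expA / expA.sum(axis=1, keepdims=True)
    soft[np.arange(len(ks)), ks] -= 1.0
    dz = soft @ (bank.c / bank.tau_k[:, None]) / len(ks)
    return loss, dz
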