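"""Instance-level contrastive losses with domain-guided positives.

The batch convention doubles every source segment into two augmented views;
view ``2i`` and ``2i+1`` come from source ``i`` and share its domain feature
vector.  For an anchor view, the positive set P(i) is its sibling view plus
S(i), the views of the nearest other sources in *domain feature space*
(Euclidean distance); the negative pool N*(i) is the remaining views, i.e.
the selected neighbours are removed from the negatives.  The multi-positive
loss averages, over the positives, a softmax term whose denominator contains
that positive plus N*(i) only.

All softmax-style terms use max-shifted log-sum-exp for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

__all__ = [
    "EmbeddingBatch", "PairAssignment", "info_nce",
    "select_domain_neighbors", "build_pair_assignment",
    "instance_loss", "instance_loss_and_grad",
]


@dataclass
class EmbeddingBatch:
    """Unit-norm projections of a doubled batch of views.

    z : (2B, dim) l2-normalized projections.
    view_to_source : (2B,) source-segment index of each view (two views per
        source).
    d : (2B, n_features) domain feature rows aligned to views (sibling views
        carry identical rows), or None when neighbour selection is unused.
    """

    z: np.ndarray
    view_to_source: np.ndarray
    d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.view_to_source = np.asarray(self.view_to_source)
        if self.z.shape[0] != len(self.view_to_source):
            raise ValidationError("z and view_to_source lengths differ")
        counts = np.bincount(self.view_to_source)
        if not np.all(counts[counts > 0] == 2):
            raise ValidationError("each source must map to exactly two views")
        nrm = np.linalg.norm(self.z, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-6):
            raise ValidationError("projection rows must be unit-norm")

    @property
    def n_views(self) -> int:
        return self.z.shape[0]

    def sibling(self, i: int) -> int:
        src = self.view_to_source[i]
        twins = np.flatnonzero(self.view_to_source == src)
        return int(twins[0] if twins[1] == i else twins[1])


@dataclass
class PairAssignment:
    """Per-anchor positive/neighbour/negative view index sets."""

    sibling: list[int]
    neighbors: list[list[int]]      # S(i)
    positives: list[list[int]]      # P(i) = {sibling} + S(i)
    negatives: list[list[int]]      # N*(i) = all views \ ({i} + P(i))


def info_nce(zi: np.ndarray, zp: np.ndarray, negatives: np.ndarray,
             tau: float) -> float:
    """Single-anchor InfoNCE: -log exp(zi.zp/t) / (exp(zi.zp/t) + sum_n exp(zi.zn/t)).

    With an empty negative set the denominator equals the numerator and the
    loss is 0.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    a_p = float(zi @ zp) / tau
    negatives = np.asarray(negatives, dtype=np.float64).reshape(-1, len(zi))
    logits = np.concatenate([[a_p], negatives @ zi / tau])
    m = logits.max()
    return float(-(a_p - m) + np.log(np.exp(logits - m).sum()))


def select_domain_neighbors(anchor: int, batch: EmbeddingBatch, count: int = 2) -> list[int]:
    """The ``count`` candidate views nearest to the anchor in domain feature space.

    Candidates exclude the anchor and its sibling view (already the primary
    positive).  Ties break by ascending view index.  Because sibling views
    share one feature row, the top-2 are normally the two views of the
    nearest other source segment.
    """
    if batch.d is None:
        raise ValidationError("batch carries no domain feature rows")
    if len(np.unique(batch.view_to_source)) < 2:
        raise ValidationError("need at least 2 source segments for neighbour selection")
    if count < 1:
        raise ValidationError("count must be >= 1")
    sib = batch.sibling(anchor)
    cand = np.array([j for j in range(batch.n_views) if j != anchor and j != sib])
    dist = np.linalg.norm(batch.d[cand] - batch.d[anchor], axis=1)
    order = np.argsort(dist, kind="stable")       # candidates are index-sorted
    return [int(j) for j in cand[order[:count]]]


def build_pair_assignment(batch: EmbeddingBatch, n_neighbors: int = 2) -> PairAssignment:
    """Assemble P(i) and N*(i) for every anchor view in the batch.

    ``n_neighbors=0`` disables domain guidance and recovers the plain
    one-positive instance discrimination setup.
    """
    all_views = set(range(batch.n_views))
    sib, nbrs, pos, neg = [], [], [], []
    for i in range(batch.n_views):
        p = batch.sibling(i)
        S = select_domain_neighbors(i, batch, n_neighbors) if n_neighbors > 0 else []
        P = [p] + S
        N = sorted(all_views - {i} - set(P))
        sib.append(p)
        nbrs.append(S)
        pos.append(P)
        neg.append(N)
    return PairAssignment(sibling=sib, neighbors=nbrs, positives=pos, negatives=neg)


def _per_anchor_terms(S_row: np.ndarray, P: list[int], N: list[int]):
    """Stable per-anchor loss terms; returns (losses over P, softmax pieces)."""
    idx = P + N
    m = S_row[idx].max() if idx else 0.0
    eN = np.exp(S_row[N] - m) if N else np.zeros(0)
    E = eN.sum()
    eP = np.exp(S_row[P] - m)
    denom = eP + E
    losses = -(S_row[P] - m) + np.log(denom)
    return losses, eP, eN, denom


def instance_loss(batch: EmbeddingBatch, pairs: PairAssignment, tau: float) -> float:
    """Multi-positive instance loss, mean over anchors.

    Per anchor: average over p* in P(i) of
    -log exp(zi.zp*/t) / (exp(zi.zp*/t) + sum_{n in N*(i)} exp(zi.zn/t)).
    """
    loss, _ = instance_loss_and_grad(batch, pairs, tau, need_grad=False)
    return loss


def instance_loss_and_grad(batch: EmbeddingBatch, pairs: PairAssignment, tau: float,
                           need_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Loss plus d(loss)/dz for every view (None when ``need_grad`` is False)."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    z = batch.z
    nV = batch.n_views
    S = (z @ z.T) / tau
    total = 0.0
    G = np.zeros((nV, nV)) if need_grad else None
    for i in range(nV):
        P, N = pairs.positives[i], pairs.negatives[i]
        if not P:
            raise ValidationError(f"anchor {i} has empty positive set")
        losses, eP, eN, denom = _per_anchor_terms(S[i], P, N)
        total += losses.mean()
        if need_grad:
            w = 1.0 / (nV * len(P))
            G[i, P] += w * (eP / denom - 1.0)
            if N:
                G[i, N] += w * (eN[None, :] / denom[:, None]).sum(axis=0)
    loss = total / nV
    if not need_grad:
        return loss, None
    dz = (G + G.T) @ z / tau
    return loss, dz
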