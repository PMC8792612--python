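"""Similarity kernel fusion (SKF) by nonlinear cross-diffusion.

Given m >= 2 similarity kernels over one entity space, SKF integrates them
into a single comprehensive kernel in three stages:

1. each kernel is column-normalized (global view Theta_u) and
   neighbor-normalized to its k nearest neighbors (local view Phi_u, a
   row-stochastic matrix supported on each entity's k most similar entities);
2. the global views are cross-diffused for a fixed number of rounds,

   ``Theta_u(t+1) = alpha * Phi_u @ mean_{r != u} Theta_r(t) @ Phi_u.T
                    + (1 - alpha) * mean_{r != u} Theta_r(0)``

   so each kernel's local structure filters the consensus of the others;
3. the diffused views are averaged and reweighted entrywise by a kNN
   consensus weight matrix W (1 where every kernel's kNN indicator agrees
   the edge is present, 0 where all agree absent, 0.5 otherwise).

The comprehensive kernel is ``S = mean(Theta_u(final)) * W`` (elementwise).
Each Theta_u is symmetrized after every update, and S is symmetrized at the
end, because column normalization and kNN selection break symmetry while
the downstream Laplacian-regularized solver expects a symmetric similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import SimilarityKernel

__all__ = [
    "FusionParams",
    "FusedKernel",
    "DRUG_FUSION_DEFAULTS",
    "DISEASE_FUSION_DEFAULTS",
    "column_normalize",
    "knn_indicator",
    "neighbor_normalize",
    "consensus_weight",
    "skf_iterate",
    "fuse_space",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionParams:
    """SKF hyperparameters for one entity space.

    k
        neighborhood size for the local views and the consensus weights.
    alpha
        diffusion weight in (0, 1): alpha of each update comes from the
        cross-diffused term, 1-alpha from the initial consensus.
    iterations
        fixed number of diffusion rounds (default 10).
    tolerance
        diagnostic threshold for the per-kernel relative-error trace;
        convergence is logged, never enforced.
    symmetrize
        symmetrize each Theta_u after every update and the final S.
    """

    k: int
    alpha: float
    iterations: int = 10
    tolerance: float = 1e-7
    symmetrize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


DRUG_FUSION_DEFAULTS = FusionParams(k=15, alpha=0.2)
DISEASE_FUSION_DEFAULTS = FusionParams(k=10, alpha=0.7)


@dataclass
class FusedKernel:
    """Output of :func:`skf_iterate`.

    ``S`` is the comprehensive kernel (Theta * W, symmetrized), ``W`` the
    consensus weight matrix with entries in {0, 0.5, 1}, ``Theta`` the
    average of the diffused kernels before weighting, and ``error_trace``
    an (iterations x m) array of per-kernel relative changes per round.
    """

    S: SimilarityKernel
    W: np.ndarray
    Theta: np.ndarray
    error_trace: np.ndarray
    params: FusionParams


def _values(K) -> np.ndarray:
    return K.values if isinstance(K, SimilarityKernel) else np.asarray(K, dtype=float)


def _ids(K, n: int) -> list[str]:
    return list(K.entity_ids) if isinstance(K, SimilarityKernel) else [str(i) for i in range(n)]


def column_normalize(K) -> np.ndarray:
    """Normalize each column to sum 1: theta(i, j) = K(i, j) / sum_v K(v, j)."""
    V = _values(K)
    sums = V.sum(axis=0)
    if (sums <= 0).any():
        j = int(np.argmax(sums <= 0))
        raise ValueError(
            f"column for entity {_ids(K, V.shape[0])[j]!r} sums to {sums[j]:g}; "
            "cannot column-normalize"
        )
    return V / sums[None, :]


def knn_indicator(K, k: int) -> np.ndarray:
    """Binary matrix with row i marking the k entities most similar to i.

    The entity itself competes like any other (its self-similarity is
    maximal in all base kernels, so it is normally selected).  Ties on the
    k-th similarity are broken by ascending entity index, which makes the
    selection deterministic across platforms.
    """
    V = _values(K)
    n = V.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n = {n}, got {k}")
    # stable argsort of -V keeps ascending original index among ties
    order = np.argsort(-V, axis=1, kind="stable")
    ind = np.zeros_like(V)
    rows = np.repeat(np.arange(n), k)
    ind[rows, order[:, :k].ravel()] = 1.0
    return ind


def neighbor_normalize(K, k: int) -> np.ndarray:
    """Row-stochastic local kernel restricted to each entity's k neighbors.

    phi(i, j) = K(i, j) I(i, j) / sum_v K(i, v) I(i, v), with I the kNN
    indicator of :func:`knn_indicator`.
    """
    V = _values(K)
    masked = V * knn_indicator(K, k)
    sums = masked.sum(axis=1)
    if (sums <= 0).any():
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"entity {_ids(K, V.shape[0])[i]!r} has zero similarity to all of "
            f"its {k} nearest neighbors; cannot neighbor-normalize"
        )
    return masked / sums[:, None]


def consensus_weight(indicators: list[np.ndarray]) -> np.ndarray:
    """Entrywise kNN agreement across kernels: 1 all-present, 0 all-absent, 0.5 mixed."""
    if len(indicators) < 2:
        raise ValueError("consensus requires at least two indicator matrices")
    shapes = {np.asarray(I).shape for I in indicators}
    if len(shapes) != 1:
        raise ValueError(f"indicator shape mismatch: {sorted(shapes)}")
    stack = np.stack([np.asarray(I, dtype=float) for I in indicators])
    W = np.full(stack.shape[1:], 0.5)
    W[stack.min(axis=0) == 1] = 1.0
    W[stack.max(axis=0) == 0] = 0.0
    return W


def skf_iterate(kernels: list[SimilarityKernel], params: FusionParams) -> FusedKernel:
    """Run the SKF cross-diffusion on m >= 2 kernels over one entity space."""
    if len(kernels) < 2:
        raise ValueError("similarity kernel fusion requires at least two kernels")
    first = kernels[0]
    ids = _ids(first, _values(first).shape[0])
    space = first.space if isinstance(first, SimilarityKernel) else "drug"
    for K in kernels[1:]:
        if isinstance(K, SimilarityKernel) and isinstance(first, SimilarityKernel):
            if K.entity_ids != first.entity_ids:
                raise ValueError("all kernels must share the same ordered entity list")
            if K.space != first.space:
                raise ValueError("all kernels must belong to the same entity space")
        elif _values(K).shape != _values(first).shape:
            raise ValueError("all kernels must have the same shape")

    m = len(kernels)
    n = len(ids)
    if not 1 <= params.k < n:
        raise ValueError(f"k must satisfy 1 <= k < n = {n}, got {params.k}")

    thetas0 = [column_normalize(K) for K in kernels]
    phis = [neighbor_normalize(K, params.k) for K in kernels]
    indicators = [knn_indicator(K, params.k) for K in kernels]

    init_consensus = [
        sum(thetas0[r] for r in range(m) if r != u) / (m - 1) for u in range(m)
    ]
    thetas = [T.copy() for T in thetas0]
    alpha = params.alpha
    error_trace = np.empty((params.iterations, m))
    for t in range(params.iterations):
        cross = [sum(thetas[r] for r in range(m) if r != u) / (m - 1) for u in range(m)]
        new = []
        for u in range(m):
            T = alpha * (phis[u] @ cross[u] @ phis[u].T) + (1.0 - alpha) * init_consensus[u]
            if params.symmetrize:
                T = (T + T.T) / 2.0
            error_trace[t, u] = np.linalg.norm(T - thetas[u]) / np.linalg.norm(thetas[u])
            new.append(T)
        thetas = new
    if error_trace[-1].max() > params.tolerance:
        logger.info(
            "SKF (%s space): final relative error %.3g above diagnostic tolerance %.3g "
            "after %d iterations",
            space, error_trace[-1].max(), params.tolerance, params.iterations,
        )

    Theta = sum(thetas) / m
    W = consensus_weight(indicators)
    S = Theta * W
    if params.symmetrize:
        S = (S + S.T) / 2.0
    fused = SimilarityKernel(S, ids, space=space, kind="fused")
    return FusedKernel(S=fused, W=W, Theta=Theta, error_trace=error_trace, params=params)


def fuse_space(kernels: list[SimilarityKernel], space: str | None = None, **overrides) -> FusedKernel:
    """:func:`skf_iterate` with per-space defaults (drug: alpha=0.2, k=15;
    disease: alpha=0.7, k=10; 10 iterations).  Keyword overrides win."""
    if space is None:
        if not kernels or not isinstance(kernels[0], SimilarityKernel):
            raise ValueError("space must be given when kernels carry no space tag")
        space = kernels[0].space
    if space == "drug":
        params = DRUG_FUSION_DEFAULTS
    elif space == "disease":
        params = DISEASE_FUSION_DEFAULTS
    else:
        raise ValueError(f"space must be 'drug' or 'disease', got {space!r}")
    if overrides:
        params = replace(params, **overrides)
    return skf_iterate(kernels, params)
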