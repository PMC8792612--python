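"""Laplacian regularized least squares (LapRLS) scoring.

Each subspace (drug, disease) fits the association matrix with a
least-squares term plus a smoothness penalty over the normalized graph
Laplacian of its comprehensive similarity kernel.  The closed form is

    F = S (S + beta L S)^{-1} Y,

with S the similarity kernel, L = D^{-1/2} (D - S) D^{-1/2} its normalized
Laplacian and Y the (training) association matrix.  The disease-subspace
solve takes Y = A directly; the drug-subspace solve runs on A^T (drugs as
rows) and transposes the result back, so both predictions live on the
diseases x drugs grid and can be blended as lam * F_disease-side +
(1 - lam) * F_drug-side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import AssociationMatrix, PredictionMatrix, SimilarityKernel
from .fusion import FusionParams, fuse_space
from .kernels import gip_kernel

__all__ = [
    "LapRLSParams",
    "normalized_laplacian",
    "laprls_solve",
    "combine_subspaces",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LapRLSParams:
    """LapRLS hyperparameters.

    beta
        weight of the Laplacian smoothness penalty (default 2^-16); applies
        to both subspaces unless overridden per call.
    lam
        blend weight of the disease-subspace prediction in the final score,
        F = lam * F_p + (1 - lam) * F_d.  Endpoints are permitted: lam = 0
        is the drug-subspace-only (orphan) mode.
    jitter
        optional diagonal ridge added to the linear system for singular S.
    """

    beta: float = 2.0**-16
    lam: float = 0.4
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")


def _values(S) -> np.ndarray:
    return S.values if isinstance(S, SimilarityKernel) else np.asarray(S, dtype=float)


def normalized_laplacian(S, tolerance: float = 1e-8) -> np.ndarray:
    """Normalized graph Laplacian L = D^{-1/2} (D - S) D^{-1/2}.

    D is the diagonal of row sums of S.  Requires S symmetric (within
    ``tolerance``), nonnegative, with strictly positive row sums; the
    result is symmetric with eigenvalues in [0, 2].
    """
    V = _values(S)
    ids = S.entity_ids if isinstance(S, SimilarityKernel) else [str(i) for i in range(V.shape[0])]
    if np.abs(V - V.T).max(initial=0.0) > tolerance:
        raise ValueError(
            f"similarity matrix is asymmetric beyond tolerance {tolerance:g}; "
            "symmetrize before building the Laplacian"
        )
    if (V < 0).any():
        raise ValueError("similarity matrix has negative entries")
    d = V.sum(axis=1)
    if (d <= 0).any():
        i = int(np.argmax(d <= 0))
        raise ValueError(f"entity {ids[i]!r} has zero total similarity; Laplacian undefined")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = (np.diag(d) - V) * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (L + L.T) / 2.0


def laprls_solve(S, L: np.ndarray, Y: np.ndarray, beta: float, jitter: float = 0.0) -> np.ndarray:
    """Closed-form LapRLS solution F = S (S + beta L S)^{-1} Y.

    Computed through a dense linear solve (never an explicit inverse).  The
    system matrix S + beta L S is a product of symmetric factors and not
    itself symmetric, so a general LU solve is used.  ``Y`` must have one
    row per entity of S.
    """
    V = _values(S)
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != V.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows but the kernel has {V.shape[0]} entities")
    M = V + beta * (L @ V)
    if jitter:
        M = M + jitter * np.eye(V.shape[0])
    try:
        X = scipy.linalg.solve(M, Y)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "LapRLS system is singular; consider a small diagonal jitter "
            "(LapRLSParams.jitter) or a different beta"
        ) from exc
    return V @ X


def combine_subspaces(Fp: PredictionMatrix, Fd: PredictionMatrix, lam: float) -> PredictionMatrix:
    """Blend the two subspace predictions: F = lam * Fp + (1 - lam) * Fd."""
    if Fp.disease_ids != Fd.disease_ids or Fp.drug_ids != Fd.drug_ids:
        raise ValueError("subspace predictions have mismatched identifier axes")
    scores = lam * Fp.scores + (1.0 - lam) * Fd.scores
    return PredictionMatrix(scores, list(Fp.disease_ids), list(Fp.drug_ids))


def _subspace_kernel(base_kernels, gip, space, fusion_params):
    kernels = list(base_kernels) + [gip]
    if len(kernels) == 1:
        # single-similarity mode: no fusion possible or needed
        return kernels[0]
    if fusion_params is None:
        return fuse_space(kernels, space=space).S
    return fuse_space(
        kernels,
        space=space,
        k=fusion_params.k,
        alpha=fusion_params.alpha,
        iterations=fusion_params.iterations,
        tolerance=fusion_params.tolerance,
        symmetrize=fusion_params.symmetrize,
    ).S


def predict(
    A_train: AssociationMatrix,
    drug_kernels=(),
    disease_kernels=(),
    *,
    drug_fusion: FusionParams | None = None,
    disease_fusion: FusionParams | None = None,
    params: LapRLSParams | None = None,
) -> PredictionMatrix:
    """Score every drug-disease pair from a training association matrix.

    The drug and disease association (GIP) kernels are recomputed from
    ``A_train`` inside this call, so masking the training matrix is all a
    cross-validation driver needs to do to avoid information leakage.
    ``drug_kernels`` / ``disease_kernels`` are the precomputed similarity
    kernels (chemical, functional, semantic).  With ``params.lam == 0`` the
    disease subspace is skipped entirely (and ``disease_kernels`` may be
    empty); symmetrically for ``lam == 1``.
    """
    params = params or LapRLSParams()
    lam = params.lam
    A = A_train.values.astype(float)
    Fp = Fd = None

    if lam > 0.0:
        gip_p = gip_kernel(A_train, "disease")
        S_p = _subspace_kernel(disease_kernels, gip_p, "disease", disease_fusion)
        L_p = normalized_laplacian(S_p)
        Fp = laprls_solve(S_p, L_p, A, params.beta, params.jitter)
    if lam < 1.0:
        gip_d = gip_kernel(A_train, "drug")
        S_d = _subspace_kernel(drug_kernels, gip_d, "drug", drug_fusion)
        L_d = normalized_laplacian(S_d)
        Fd = laprls_solve(S_d, L_d, A.T, params.beta, params.jitter).T

    if Fp is None:
        scores = Fd
    elif Fd is None:
        scores = Fp
    else:
        scores = lam * Fp + (1.0 - lam) * Fd
    return PredictionMatrix(scores, list(A_train.disease_ids), list(A_train.drug_ids))
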