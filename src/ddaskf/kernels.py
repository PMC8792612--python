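"""Base similarity kernels.

Five base kernels feed the fusion stage.  On the drug side: a chemical
kernel (Jaccard coefficient between fingerprint bit sets), a functional
kernel (Jaccard between annotation term sets) and an association kernel
(Gaussian interaction profile, GIP, over the columns of the association
matrix).  On the disease side: a semantic kernel (consumed precomputed) and
a GIP kernel over the rows of the association matrix.

The GIP bandwidth gamma is normalized so that the average squared profile
norm equals 1/gamma: gamma = n / sum_i ||profile_i||^2.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import AssociationMatrix, BinaryProfileSet, SimilarityKernel

__all__ = ["jaccard_kernel", "gip_bandwidth", "gip_kernel", "validate_kernel"]

logger = logging.getLogger(__name__)


def jaccard_kernel(profiles: BinaryProfileSet, space: str = "drug", kind: str = "chemical") -> SimilarityKernel:
    """Pairwise Jaccard similarity over the 1-bit sets of binary profiles.

    ``K[i, j] = |P_i & P_j| / |P_i | P_j|``.  A pair of two all-zero
    profiles has no shared evidence and is assigned similarity 0 (including
    the diagonal entry of an all-zero profile), with a warning.
    """
    P = profiles.profiles.astype(np.float64)
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    empty_pair = union == 0
    if empty_pair.any():
        n_empty = int((sizes == 0).sum())
        warnings.warn(
            f"{n_empty} all-zero {profiles.namespace} profile(s): pairwise "
            "similarity for empty-vs-empty pairs is defined as 0",
            stacklevel=2,
        )
    K = np.divide(inter, union, out=np.zeros_like(inter), where=~empty_pair)
    return SimilarityKernel(K, profiles.entity_ids, space=space, kind=kind)


def _space_profiles(A, space: str) -> np.ndarray:
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    if space == "drug":
        return values.T.astype(np.float64)
    if space == "disease":
        return values.astype(np.float64)
    raise ValueError(f"space must be 'drug' or 'disease', got {space!r}")


def gip_bandwidth(A, space: str) -> float:
    """GIP bandwidth gamma = n / sum of squared profile norms in ``space``.

    Accepts an :class:`AssociationMatrix` or a raw (possibly real-valued)
    diseases x drugs array.
    """
    profiles = _space_profiles(A, space)
    total = float((profiles**2).sum())
    if total == 0.0:
        raise ValueError(f"cannot set GIP bandwidth: every {space} profile is all-zero")
    return profiles.shape[0] / total


def gip_kernel(A, space: str) -> SimilarityKernel:
    """Gaussian interaction profile kernel K(i,j) = exp(-gamma ||p_i - p_j||^2)."""
    profiles = _space_profiles(A, space)
    gamma = gip_bandwidth(A, space)
    sq_norms = (profiles**2).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    d2 = np.maximum(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0  # guard against BLAS rounding asymmetry
    np.fill_diagonal(d2, 0.0)
    K = np.exp(-gamma * d2)
    if isinstance(A, AssociationMatrix):
        ids = A.drug_ids if space == "drug" else A.disease_ids
    else:
        ids = [str(i) for i in range(profiles.shape[0])]
    return SimilarityKernel(K, ids, space=space, kind="association")


def validate_kernel(K: SimilarityKernel, tolerance: float = 1e-8) -> list[str]:
    """Diagnostic check of kernel invariants; returns a list of violations.

    Checked: finiteness, nonnegativity, symmetry within ``tolerance`` and
    (for base, non-fused kernels) a unit diagonal within ``tolerance``.
    An empty list means the kernel is clean.
    """
    violations: list[str] = []
    V = K.values
    if not np.isfinite(V).all():
        n_bad = int((~np.isfinite(V)).sum())
        violations.append(f"{n_bad} non-finite entries (NaN/Inf)")
    neg = V < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        violations.append(
            f"{int(neg.sum())} negative entries (first at "
            f"{K.entity_ids[i]!r}, {K.entity_ids[j]!r}: {V[i, j]:.3g})"
        )
    with np.errstate(invalid="ignore"):
        asym = np.abs(V - V.T)
    if np.nanmax(asym, initial=0.0) > tolerance:
        i, j = np.argwhere(asym > tolerance)[0]
        violations.append(
            f"asymmetry beyond tolerance {tolerance:g} (max |K-K^T| = "
            f"{np.nanmax(asym):.3g} at {K.entity_ids[i]!r}, {K.entity_ids[j]!r})"
        )
    if K.kind != "fused":
        diag_err = np.abs(np.diag(V) - 1.0)
        if np.nanmax(diag_err, initial=0.0) > tolerance:
            i = int(np.argmax(diag_err))
            violations.append(
                f"non-unit diagonal for base kernel (entry {K.entity_ids[i]!r}: {V[i, i]:.3g})"
            )
    for v in violations:
        logger.debug("kernel %s/%s: %s", K.space, K.kind, v)
    return violations
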