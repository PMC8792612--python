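"""Typed containers shared across the package.

The central object is the binary association matrix ``A`` (diseases as rows,
drugs as columns).  Everything else — similarity kernels, binary feature
profiles, prediction score matrices — carries the same ordered identifier
axes so that downstream code can verify conformability instead of trusting
positional alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "BinaryProfileSet",
    "SimilarityKernel",
    "PredictionMatrix",
    "Dataset",
    "SPACES",
    "KERNEL_KINDS",
]

SPACES = ("drug", "disease")
KERNEL_KINDS = ("chemical", "functional", "association", "semantic", "fused")


def _as_ids(ids: Sequence, what: str) -> list[str]:
    out = [str(x) for x in ids]
    if len(set(out)) != len(out):
        seen, dupes = set(), []
        for x in out:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dupes))[:5]}")
    if not out:
        raise ValueError(f"empty {what} identifier list")
    return out


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    if not np.isin(values, (0, 1)).all():
        idx = np.argwhere(~np.isin(values, (0, 1)))
        i, j = (int(idx[0][0]), int(idx[0][1])) if values.ndim == 2 else (int(idx[0][0]), -1)
        raise ValueError(
            f"{what} must contain only 0/1 entries; offending value "
            f"{values[tuple(idx[0])]!r} at row {i}, column {j}"
        )
    return values.astype(np.int8)


@dataclass
class AssociationMatrix:
    """Binary diseases x drugs adjacency matrix with identifier axes.

    ``values[i, j] == 1`` means disease ``disease_ids[i]`` is a known
    indication of drug ``drug_ids[j]``.  Drug association profiles are the
    columns of ``values``; disease profiles are the rows.
    """

    values: np.ndarray
    disease_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        self.disease_ids = _as_ids(self.disease_ids, "disease")
        self.drug_ids = _as_ids(self.drug_ids, "drug")
        if self.values.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.drug_ids)} drugs"
            )
        self.values = _check_binary(self.values, "association matrix")

    @property
    def n_diseases(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    def drug_profiles(self) -> np.ndarray:
        """Association profiles of drugs: one row per drug (columns of A)."""
        return self.values.T

    def disease_profiles(self) -> np.ndarray:
        """Association profiles of diseases: one row per disease (rows of A)."""
        return self.values

    def positives(self) -> np.ndarray:
        """(n_pos, 2) array of (disease index, drug index) known associations."""
        return np.argwhere(self.values == 1)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), list(self.disease_ids), list(self.drug_ids))


@dataclass
class BinaryProfileSet:
    """Binary feature profiles (fingerprint bits, annotation terms) per entity."""

    entity_ids: list[str]
    profiles: np.ndarray
    namespace: str = "features"

    def __post_init__(self) -> None:
        self.entity_ids = _as_ids(self.entity_ids, "entity")
        self.profiles = np.asarray(self.profiles)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != len(self.entity_ids):
            raise ValueError("profiles must be a 2-D matrix with one row per entity")
        self.profiles = _check_binary(self.profiles, f"{self.namespace} profiles")

    @property
    def n_entities(self) -> int:
        return self.profiles.shape[0]


@dataclass
class SimilarityKernel:
    """Square nonnegative similarity matrix over one entity space.

    Base (non-fused) kernels are expected to be symmetric with unit diagonal;
    use :func:`ddaskf.kernels.validate_kernel` for a diagnostic report.
    """

    values: np.ndarray
    entity_ids: list[str]
    space: str = "drug"
    kind: str = "association"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = _as_ids(self.entity_ids, "entity")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} does not match {n} entities")
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kind must be one of {KERNEL_KINDS}, got {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "SimilarityKernel":
        return SimilarityKernel(self.values.copy(), list(self.entity_ids), self.space, self.kind)


@dataclass
class PredictionMatrix:
    """Real-valued diseases x drugs score matrix produced by the model."""

    scores: np.ndarray
    disease_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.disease_ids = _as_ids(self.disease_ids, "disease")
        self.drug_ids = _as_ids(self.drug_ids, "drug")
        if self.scores.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise ValueError("score matrix shape does not match identifier axes")
        if not np.isfinite(self.scores).all():
            raise ValueError("prediction scores must be finite")


@dataclass
class Dataset:
    """A complete modelling input: associations plus precomputed kernels.

    ``drug_kernels`` / ``disease_kernels`` hold the precomputed similarity
    kernels (chemical, functional, semantic).  The association (GIP) kernels
    are *not* stored here — they depend on the training split and are
    recomputed from the masked association matrix at prediction time.
    """

    association: AssociationMatrix
    drug_kernels: list[SimilarityKernel] = field(default_factory=list)
    disease_kernels: list[SimilarityKernel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k in self.drug_kernels:
            if k.entity_ids != self.association.drug_ids:
                raise ValueError(f"drug kernel ({k.kind}) entity ids do not match association drug ids")
        for k in self.disease_kernels:
            if k.entity_ids != self.association.disease_ids:
                raise ValueError(f"disease kernel ({k.kind}) entity ids do not match association disease ids")

    def with_association(self, association: AssociationMatrix) -> "Dataset":
        return replace(self, association=association)
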