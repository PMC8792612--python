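"""TSV readers and writers for the package's matrix dialects.

One on-disk dialect is used everywhere: tab-delimited UTF-8 text with a
header row of column identifiers and a first column of row identifiers
(top-left cell ignored), '.' decimal, no quoting.  Association and profile
matrices carry 0/1 cells; kernels are square with identical row and column
identifier lists.  Real values are written with 17 significant digits so a
write/read round trip reproduces every float64 exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    AssociationMatrix,
    BinaryProfileSet,
    PredictionMatrix,
    SimilarityKernel,
)

__all__ = ["read_matrix", "write_matrix", "read_plain_matrix"]


def _parse_tsv(path: str) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if not col_ids:
        raise ValueError(f"{path}: header row carries no column identifiers")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} fields, expected {len(header)}"
            )
        row_ids.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError:
            for col_id, cell in zip(col_ids, parts[1:]):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {parts[0]!r}, "
                        f"column {col_id!r}"
                    ) from None
            raise
    return row_ids, col_ids, np.array(rows, dtype=float)


def read_matrix(path: str, kind: str, *, space: str = "drug",
                kernel_kind: str = "association", namespace: str = "features"):
    """Read a typed matrix from the TSV dialect.

    ``kind`` selects the container and its invariant checks:
    ``"association"`` (binary, diseases x drugs), ``"kernel"`` (square,
    row IDs equal to column IDs; tagged with ``space``/``kernel_kind``) or
    ``"profiles"`` (binary, entities x features).
    """
    row_ids, col_ids, values = _parse_tsv(path)
    if kind == "association":
        if not np.isin(values, (0.0, 1.0)).all():
            i, j = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
            raise ValueError(
                f"{path}: association cell must be 0/1, got {values[i, j]:g} at "
                f"row {row_ids[i]!r}, column {col_ids[j]!r}"
            )
        return AssociationMatrix(values.astype(np.int8), row_ids, col_ids)
    if kind == "kernel":
        if row_ids != col_ids:
            raise ValueError(
                f"{path}: kernel row identifiers differ from column identifiers "
                f"(first mismatch: {next((a, b) for a, b in zip(row_ids, col_ids) if a != b)})"
            )
        return SimilarityKernel(values, row_ids, space=space, kind=kernel_kind)
    if kind == "profiles":
        if not np.isin(values, (0.0, 1.0)).all():
            i, j = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
            raise ValueError(
                f"{path}: profile cell must be 0/1, got {values[i, j]:g} at "
                f"row {row_ids[i]!r}, column {col_ids[j]!r}"
            )
        return BinaryProfileSet(row_ids, values.astype(np.int8), namespace=namespace)
    raise ValueError(f"kind must be 'association', 'kernel' or 'profiles', got {kind!r}")


def write_matrix(obj, path: str) -> None:
    """Write a typed matrix in the TSV dialect (round-trip safe)."""
    if isinstance(obj, AssociationMatrix):
        frame = pd.DataFrame(obj.values.astype(int), index=obj.disease_ids, columns=obj.drug_ids)
        float_format = None
    elif isinstance(obj, BinaryProfileSet):
        columns = [f"f{j}" for j in range(obj.profiles.shape[1])]
        frame = pd.DataFrame(obj.profiles.astype(int), index=obj.entity_ids, columns=columns)
        float_format = None
    elif isinstance(obj, SimilarityKernel):
        frame = pd.DataFrame(obj.values, index=obj.entity_ids, columns=obj.entity_ids)
        float_format = "%.17g"
    elif isinstance(obj, PredictionMatrix):
        frame = pd.DataFrame(obj.scores, index=obj.disease_ids, columns=obj.drug_ids)
        float_format = "%.17g"
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    frame.to_csv(path, sep="\t", float_format=float_format, index_label="")


def read_plain_matrix(path: str) -> np.ndarray:
    """Best-effort reader for headerless whitespace-delimited numeric matrices.

    Escape hatch (CLI flag ``--no-header``) for externally deposited
    matrices that lack identifier axes; callers must supply identifiers
    themselves.  Not part of the validated TSV dialect.
    """
    values = np.loadtxt(path, ndmin=2)
    return values
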