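"""Run configuration: a flat YAML file mirrored into a dataclass."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Flat run settings shared by the CLI subcommands.

    Paths are optional (subcommands check the ones they need); numeric
    defaults are the calibrated model defaults: drug-space fusion
    alpha=0.2/k=15, disease-space alpha=0.7/k=10, 10 diffusion rounds,
    LapRLS beta=2^-16 and blend lam=0.4.
    """

    association: str | None = None
    drug_kernels: list[str] = field(default_factory=list)
    disease_kernels: list[str] = field(default_factory=list)
    output_dir: str = "."
    seed: int = 0
    drug_alpha: float = 0.2
    drug_k: int = 15
    disease_alpha: float = 0.7
    disease_k: int = 10
    iterations: int = 10
    beta: float = 2.0**-16
    lam: float = 0.4
    jitter: float = 0.0
    scheme: str = "association_cv"
    n_folds: int = 10
    n_repeats: int = 5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.drug_alpha < 1.0) or not (0.0 < self.disease_alpha < 1.0):
            raise ValueError("fusion alpha values must lie in (0, 1)")
        if self.drug_k < 1 or self.disease_k < 1 or self.iterations < 1:
            raise ValueError("k and iteration counts must be positive")
        if self.beta < 0 or not (0.0 <= self.lam <= 1.0) or self.jitter < 0:
            raise ValueError("require beta >= 0, 0 <= lam <= 1, jitter >= 0")
        for path in [self.association, *self.drug_kernels, *self.disease_kernels]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"configured input does not exist: {path}")


def load_config(path: str) -> RunConfig:
    """Load a flat-key YAML file into a :class:`RunConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
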