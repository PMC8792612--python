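"""Self-contained synthetic datasets with planted block structure.

The generator makes the model's core assumption — similar drugs treat
similar diseases — literally true: drugs and diseases are assigned to
latent blocks, associations are dense within matched blocks and sparse
outside, and every feature channel (two drug binary-profile sets and a
disease "semantic" kernel) is derived from noisy copies of per-block
templates.  Every base kernel therefore carries recoverable signal about
the same latent structure, which is exactly what the fusion stage is meant
to exploit.  :func:`shuffle_labels` destroys that structure while
preserving the marginal association count, providing a matched null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import AssociationMatrix, BinaryProfileSet, Dataset, SimilarityKernel
from .kernels import jaccard_kernel

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "shuffle_labels"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults give a 40 diseases x 60 drugs matrix over 4 blocks with a
    within-block association probability of 0.3 against a 0.01 background,
    128-bit profiles and a 5% bit-flip noise — a small instance whose block
    signal is strong but far from noiseless.
    """

    n_drugs: int = 60
    n_diseases: int = 40
    n_blocks: int = 4
    density_in: float = 0.3
    density_out: float = 0.01
    n_features: int = 128
    feature_noise: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_diseases, self.n_blocks, self.n_features) < 1:
            raise ValueError("counts must be positive")
        if self.n_blocks > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_blocks cannot exceed the smaller entity count")
        if not (0.0 <= self.density_out < self.density_in <= 1.0):
            raise ValueError("require 0 <= density_out < density_in <= 1")
        if not (0.0 <= self.feature_noise < 0.5):
            raise ValueError("feature_noise must lie in [0, 0.5)")


@dataclass
class SyntheticDataset:
    """Generated instance plus its latent block assignments."""

    association: AssociationMatrix
    fingerprint_profiles: BinaryProfileSet
    annotation_profiles: BinaryProfileSet
    disease_semantic: SimilarityKernel
    drug_blocks: np.ndarray
    disease_blocks: np.ndarray
    config: SyntheticConfig

    def to_dataset(self) -> Dataset:
        """Bundle as a modelling input: Jaccard kernels from the two drug
        profile sets plus the disease semantic kernel."""
        chemical = jaccard_kernel(self.fingerprint_profiles, space="drug", kind="chemical")
        functional = jaccard_kernel(self.annotation_profiles, space="drug", kind="functional")
        return Dataset(
            association=self.association,
            drug_kernels=[chemical, functional],
            disease_kernels=[self.disease_semantic],
        )


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks (so a noiseless matrix is block-diagonal)."""
    out = np.empty(n, dtype=int)
    for b, idx in enumerate(np.array_split(np.arange(n), n_blocks)):
        out[idx] = b
    return out


def _noisy_profiles(rng, blocks, n_features, noise) -> np.ndarray:
    templates = (rng.random((blocks.max() + 1, n_features)) < 0.5).astype(np.int8)
    base = templates[blocks]
    flips = rng.random(base.shape) < noise
    return np.where(flips, 1 - base, base).astype(np.int8)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a planted-block dataset, fully reproducible from ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    drug_blocks = _block_assignment(config.n_drugs, config.n_blocks)
    disease_blocks = _block_assignment(config.n_diseases, config.n_blocks)

    match = disease_blocks[:, None] == drug_blocks[None, :]
    prob = np.where(match, config.density_in, config.density_out)
    A = (rng.random(prob.shape) < prob).astype(np.int8)

    drug_ids = [f"DR{j:04d}" for j in range(config.n_drugs)]
    disease_ids = [f"DI{i:04d}" for i in range(config.n_diseases)]
    association = AssociationMatrix(A, disease_ids, drug_ids)

    fingerprints = BinaryProfileSet(
        drug_ids,
        _noisy_profiles(rng, drug_blocks, config.n_features, config.feature_noise),
        namespace="fingerprint-bits",
    )
    annotations = BinaryProfileSet(
        drug_ids,
        _noisy_profiles(rng, drug_blocks, config.n_features, config.feature_noise),
        namespace="annotation-terms",
    )
    disease_profiles = BinaryProfileSet(
        disease_ids,
        _noisy_profiles(rng, disease_blocks, config.n_features, config.feature_noise),
        namespace="semantic-terms",
    )
    semantic = jaccard_kernel(disease_profiles, space="disease", kind="semantic")

    return SyntheticDataset(
        association=association,
        fingerprint_profiles=fingerprints,
        annotation_profiles=annotations,
        disease_semantic=semantic,
        drug_blocks=drug_blocks,
        disease_blocks=disease_blocks,
        config=config,
    )


def shuffle_labels(dataset, seed: int):
    """Null model: permute the association cells uniformly, kernels untouched.

    The positive count is preserved exactly while any relationship between
    the associations and the similarity structure is destroyed.  Accepts a
    :class:`SyntheticDataset` or a :class:`~ddaskf.containers.Dataset` and
    returns the same type with only the association matrix replaced.
    """
    A = dataset.association
    rng = np.random.default_rng(seed)
    flat = A.values.ravel()
    shuffled = flat[rng.permutation(flat.size)].reshape(A.values.shape)
    new_A = AssociationMatrix(shuffled.copy(), list(A.disease_ids), list(A.drug_ids))
    if isinstance(dataset, Dataset):
        return dataset.with_association(new_A)
    return replace(dataset, association=new_A)
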