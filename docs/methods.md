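# Methods

## Problem and model

The package predicts unobserved drug–disease associations from a binary
association matrix A (diseases × drugs) and several similarity matrices per
entity space, under the working assumption that similar drugs treat
similar diseases. The pipeline has three stages: base kernel construction,
similarity kernel fusion (SKF), and Laplacian regularized least squares
(LapRLS) scoring in two subspaces.

### Base kernels

* **Jaccard kernels** (drug chemical, drug functional) are computed from
  binary feature profiles: `K(i,j) = |P_i ∩ P_j| / |P_i ∪ P_j|` over the
  sets of 1-bits. A pair of two all-zero profiles carries no shared
  evidence; its similarity is defined as 0 (with a warning) — this includes
  the diagonal entry of an all-zero profile, the only case where a base
  kernel's diagonal is not 1.
* **GIP kernels** (drug association, disease association) are Gaussian
  kernels over association profiles — columns of A for drugs, rows for
  diseases — with bandwidth `γ = n / Σ_i ‖profile_i‖²`, i.e. the average
  squared profile norm is 1/γ. The squared-distance matrix is computed via
  Gram identities, explicitly symmetrized, and its diagonal pinned to 0, so
  the kernel is exactly symmetric with unit diagonal.
* **Precomputed kernels** (semantic, or externally supplied chemical /
  functional matrices) are validated (`validate_kernel`: finiteness,
  nonnegativity, symmetry, unit diagonal for base kernels) but never
  silently modified.

### Similarity kernel fusion

Each kernel yields a column-stochastic global view Θ_u and a
row-stochastic local view Φ_u supported on each entity's k most similar
entities (self included — self-similarity is maximal in every base kernel,
and keeping the diagonal mass in Φ stabilizes the diffusion). The update

    Θ_u(t+1) = α Φ_u (Σ_{r≠u} Θ_r(t) / (m−1)) Φ_uᵀ + (1−α) (Σ_{r≠u} Θ_r(0) / (m−1))

runs simultaneously over all u for a fixed 10 rounds. The 1/(m−1) factor is
the average over the *other* kernels, making the same formula serve the
three-kernel drug space and the two-kernel disease space. The fused result
is `S = mean_u Θ_u(final) ∘ W`, with W the entrywise kNN consensus
(1 all-agree-present, 0 all-agree-absent, ½ otherwise).

Numerical choices:

* **Symmetrization.** Column normalization and kNN restriction break
  symmetry, while the downstream Laplacian requires a symmetric similarity;
  each Θ_u is symmetrized ((X+Xᵀ)/2) after every update and S at the end,
  as is standard in the cross-diffusion literature this construction
  follows. The behaviour is switchable (`FusionParams.symmetrize`).
* **Tie-breaking.** kNN ties on the k-th similarity are resolved by
  ascending entity index (a stable argsort), making neighborhoods
  deterministic across platforms. A consequence: exact permutation
  equivariance holds only when no row has a tie at its kNN boundary; tied
  boundaries (common with integer-valued GIP distances) may select
  different neighbor sets after relabeling.
* **Stopping.** The per-kernel relative change `‖Θ_u(t+1)−Θ_u(t)‖/‖Θ_u(t)‖`
  is recorded every round and logged against a diagnostic tolerance
  (default 1e−7), but never used to stop early: the iteration count is
  fixed at 10. On the default synthetic instance the trace falls from
  ~3.6e−1 to ~1.5e−8 over the 10 rounds.
* No re-normalization of Θ_u between rounds; only the final averaging and
  consensus weighting are applied.

### LapRLS scoring

With D the diagonal of row sums of S, the normalized Laplacian is
`L = D^(−1/2) (D − S) D^(−1/2)` (symmetric, eigenvalues in [0, 2]; zero row
sums are an error naming the entity). The subspace prediction is the
closed form `F = S (S + β L S)^(−1) Y`, the minimizer of
`‖Y − Sc‖²_F + β tr(cᵀ S L S c)` under F = Sc. It is computed by a dense
LU solve — the system matrix is a product of two symmetric factors and not
itself symmetric — never an explicit inverse; an optional diagonal jitter
(default 0) is available for singular S. The disease-subspace solve takes
Y = A; the drug-subspace solve runs on Aᵀ and transposes back, the unique
orientation in which both predictions share the diseases × drugs grid. The
final score is `λ F_p + (1−λ) F_d`, blended raw (no per-subspace score
normalization). λ endpoints are permitted: λ = 0 uses drug similarities
only (orphan mode), λ = 1 disease similarities only.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α (drug / disease) | 0.2 / 0.7 | diffusion weight vs. initial consensus |
| k (drug / disease) | 15 / 10 | neighborhood size (fusion and consensus) |
| iterations | 10 | fixed diffusion rounds |
| β | 2⁻¹⁶ | Laplacian penalty weight, both subspaces (independently configurable) |
| λ | 0.4 | disease-subspace blend weight |
| jitter | 0 | optional ridge for singular fused kernels |

β is small by design: for a well-conditioned S the prediction behaves as
`(I + βL)^(−1) Y ≈ Y − βLY`, so known cells stay near their training value
while unknown cells receive the graph-smoothed propagation term whose
*ranking* is essentially β-invariant.

## Evaluation protocols

* **Novel association CV** partitions the known-association cells into
  folds; each fold's positives are reset to 0 for training and evaluated
  against all pairs never observed as positive (test-fold positives are
  excluded from the negatives).
* **Novel drug CV** partitions whole drug columns; a held-out drug trains
  with an all-zero profile and is evaluated within its own columns.
* **Leakage control.** The GIP kernels are recomputed from the masked
  matrix inside every fold (asserted programmatically); the precomputed
  kernels do not depend on A and are never masked.
* **Metrics.** AUROC is the Mann–Whitney pair statistic (ties 0.5); AUPR is
  the step-interpolated precision–recall area (average-precision
  convention); SEN/SPE/PRE/ACC/F1/MCC are reported at the F1-maximizing
  threshold, scanning every distinct score value with "score strictly
  greater than threshold ⇒ predicted positive" and breaking F1 ties toward
  the larger threshold. MCC returns 0 (with a warning) when its denominator
  vanishes. Repeated CV pools all folds' test scores within a repeat before
  computing each metric and reports mean ± sd across repeats; per-fold
  averaging is available via `pooling="per_fold"`.
* **Orphan mode** removes a drug's entire column before kernel
  recomputation and scores with λ = 0, ranking its candidate diseases.

## Synthetic data

The generator plants the structure the model assumes: drugs and diseases
are assigned to contiguous, near-equal latent blocks; associations are
Bernoulli(0.3) within matched blocks and Bernoulli(0.01) outside; the two
drug profile sets and the disease "semantic" profiles are per-block
128-bit templates with independent 5% bit flips, and the semantic kernel is
the Jaccard kernel of the disease profiles. Every base kernel therefore
carries recoverable signal about the same latent structure. The 128-bit
length keeps within-block Jaccard similarity well separated from
between-block similarity at 5% flip noise while staying cheap;
`shuffle_labels` permutes the association cells uniformly (positive count
preserved, kernels untouched) as a matched null.

What the generator does **not** emulate: real fingerprint bit marginals,
annotation sparsity, phenotype-ontology similarity profiles, or the heavy
degree skew of curated association data. Passing tests on this data show
the pipeline recovers planted low-rank block structure without leakage —
not that it attains any particular performance on curated datasets.

Default problem sizes (40 diseases × 60 drugs, 10 folds, 5 repeats) were
chosen so a full cross-validation study runs in seconds while leaving
each fold enough positives (~18) for stable ranking metrics.

## Known limitations

* Dense linear algebra throughout: O(n³) solves per fold; no sparse or
  iterative paths for very large kernels.
* Exact permutation equivariance is limited by deterministic tie-breaking
  (see above); ranking output is deterministic but depends on input order
  where similarities tie.
* The fused kernel is not guaranteed positive semidefinite (consensus
  weighting is an elementwise product); LapRLS only requires the linear
  system to be solvable, and a jitter is available for degenerate cases.
* The deposited-data reader (`read_plain_matrix`, CLI `--no-header`) is a
  best-effort shim for headerless numeric matrices and performs no
  identifier validation.
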