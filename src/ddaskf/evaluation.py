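"""Cross-validation protocols, ranking metrics and case-study ranking.

Two cross-validation schemes are provided:

``association_cv``
    the known association *cells* are partitioned into folds; each fold's
    positives are reset to 0 in the training matrix and must be recovered
    among all pairs never observed as positive (novel association
    prediction).
``drug_cv``
    whole drug *columns* are partitioned; a held-out drug enters training
    with an all-zero profile and its true indications must be recovered
    within its column (novel drug prediction).

In both schemes the association (GIP) kernels are recomputed from the
masked matrix inside :func:`ddaskf.laprls.predict`, so no information from
the held-out cells can reach the training-side kernels.  The precomputed
chemical/functional/semantic kernels do not depend on the association
matrix and are never masked.

Metrics: AUROC (Mann-Whitney pair statistic, ties counted 0.5), AUPR
(step-interpolated area under precision-recall), and a thresholded suite
(SEN/SPE/PRE/ACC/F1/MCC) at the F1-maximizing threshold, where a pair is
predicted positive when its score is strictly greater than the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import AssociationMatrix, Dataset, PredictionMatrix
from .fusion import FusionParams
from .laprls import LapRLSParams, predict

__all__ = [
    "FoldSpec",
    "MetricReport",
    "CVResult",
    "make_folds",
    "mask_fold",
    "auroc",
    "aupr",
    "threshold_metrics",
    "run_cv",
    "top_k_candidates",
    "orphan_predict",
]

logger = logging.getLogger(__name__)

SCHEMES = ("association_cv", "drug_cv")


@dataclass
class FoldSpec:
    """A reproducible fold partition.

    For ``association_cv`` each fold is an (m, 2) array of held-out
    (disease index, drug index) cells; for ``drug_cv`` a 1-D array of
    held-out drug column indices.
    """

    scheme: str
    n_folds: int
    seed: int
    folds: list[np.ndarray]


@dataclass
class MetricReport:
    """Metric suite for one scored evaluation set."""

    auroc: float
    aupr: float
    sen: float
    spe: float
    pre: float
    acc: float
    f1: float
    mcc: float
    threshold: float
    fold: str = ""
    repeat: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "auroc": self.auroc, "aupr": self.aupr, "sen": self.sen,
            "spe": self.spe, "pre": self.pre, "acc": self.acc,
            "f1": self.f1, "mcc": self.mcc, "threshold": self.threshold,
        }


@dataclass
class CVResult:
    """Per-repeat (or per-fold) reports plus a mean +/- sd summary."""

    reports: list[MetricReport]
    summary: dict[str, tuple[float, float]]
    scheme: str = ""
    n_folds: int = 0
    n_repeats: int = 0


def make_folds(A: AssociationMatrix, scheme: str = "association_cv",
               n_folds: int = 10, seed: int = 0) -> FoldSpec:
    """Randomly partition association cells or drug columns into near-equal folds."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    if scheme == "association_cv":
        pos = A.positives()
        if n_folds > len(pos):
            raise ValueError(
                f"cannot split {len(pos)} known associations into {n_folds} folds"
            )
        perm = rng.permutation(len(pos))
        folds = [pos[idx] for idx in np.array_split(perm, n_folds)]
    else:
        if n_folds > A.n_drugs:
            raise ValueError(f"cannot split {A.n_drugs} drugs into {n_folds} folds")
        perm = rng.permutation(A.n_drugs)
        folds = [np.sort(idx) for idx in np.array_split(perm, n_folds)]
    return FoldSpec(scheme=scheme, n_folds=n_folds, seed=seed, folds=folds)


def mask_fold(A: AssociationMatrix, fold: np.ndarray) -> AssociationMatrix:
    """Return a copy of A with the fold's prior knowledge reset to unknown.

    A 2-D fold (cells) zeroes the held-out cells; a 1-D fold (drug columns)
    zeroes entire columns.  The input matrix is left untouched.
    """
    fold = np.asarray(fold)
    masked = A.copy()
    if fold.size == 0:
        return masked
    if fold.ndim == 2:
        masked.values[fold[:, 0], fold[:, 1]] = 0
    elif fold.ndim == 1:
        masked.values[:, fold] = 0
    else:
        raise ValueError("fold must be a 1-D (columns) or 2-D (cells) index array")
    return masked


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ranking metrics")
    return n_pos, n_neg


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n_pos, n_neg = _check_classes(labels)
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve.

    Equals sum_i (R_i - R_{i-1}) P_i over the distinct score thresholds in
    descending order (the average-precision convention).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n_pos, _ = _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    cum_tp = np.cumsum(y)
    ends = np.flatnonzero(np.r_[s[1:] != s[:-1], True])  # last index of each tie group
    precision = cum_tp[ends] / (ends + 1.0)
    recall = cum_tp[ends] / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def _mcc(tp, tn, fp, fn) -> float:
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        warnings.warn("MCC denominator is zero; returning 0", stacklevel=3)
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def threshold_metrics(scores, labels, fold: str = "", repeat: int = 0) -> MetricReport:
    """Confusion-matrix metrics at the F1-maximizing threshold.

    Every distinct score value is a candidate threshold; a pair is
    predicted positive when its score is strictly greater than the
    threshold.  Among F1 ties the largest threshold (fewest predicted
    positives) is kept.  AUROC/AUPR are included for convenience.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n_pos, n_neg = _check_classes(labels)

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    cum_tp = np.cumsum(y)
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])  # first index of each tie group
    thresholds = s[starts]          # descending distinct values
    n_pred = starts.astype(float)   # count of scores strictly greater than the threshold
    tp = np.r_[0.0, cum_tp][starts]
    fp = n_pred - tp
    fn = n_pos - tp
    tn = n_neg - fp

    with np.errstate(divide="ignore", invalid="ignore"):
        sen = np.where(n_pos > 0, tp / n_pos, 0.0)
        pre = np.where(n_pred > 0, tp / n_pred, 0.0)
        f1 = np.where(pre + sen > 0, 2 * pre * sen / (pre + sen), 0.0)
    best = int(np.argmax(f1))  # first max = largest threshold among ties
    tp_b, tn_b, fp_b, fn_b = tp[best], tn[best], fp[best], fn[best]

    return MetricReport(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        sen=float(sen[best]),
        spe=float(tn_b / n_neg),
        pre=float(pre[best]),
        acc=float((tp_b + tn_b) / (n_pos + n_neg)),
        f1=float(f1[best]),
        mcc=_mcc(tp_b, tn_b, fp_b, fn_b),
        threshold=float(thresholds[best]),
        fold=fold,
        repeat=repeat,
    )


def _repeat_seed(seed: int, repeat: int) -> int:
    return int(np.random.SeedSequence([seed, repeat]).generate_state(1)[0] % (2**31))


def _fold_eval_sets(A, F, fold, scheme, never_pos):
    """Scores and labels of one fold's evaluation universe."""
    if scheme == "association_cv":
        pos_scores = F.scores[fold[:, 0], fold[:, 1]]
        neg_scores = F.scores[never_pos]
    else:
        sub_scores = F.scores[:, fold]
        sub_labels = A.values[:, fold]
        pos_scores = sub_scores[sub_labels == 1]
        neg_scores = sub_scores[sub_labels == 0]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(pos_scores.size, dtype=np.int8),
                             np.zeros(neg_scores.size, dtype=np.int8)])
    return scores, labels


def run_cv(
    dataset: Dataset,
    scheme: str = "association_cv",
    n_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    *,
    drug_fusion: FusionParams | None = None,
    disease_fusion: FusionParams | None = None,
    params: LapRLSParams | None = None,
    pooling: str = "pooled",
) -> CVResult:
    """Repeated cross-validation with leakage-safe kernel recomputation.

    Per fold the held-out prior knowledge is masked, the GIP kernels are
    rebuilt from the masked matrix, the fused model is refit and the
    held-out pairs are scored.  With ``pooling="pooled"`` (default) all
    folds' test scores within a repeat are pooled before computing each
    metric and one report is emitted per repeat; with ``pooling="per_fold"``
    one report is emitted per fold.  The summary maps each metric to its
    (mean, sd) across repeats (per-fold reports are first averaged within
    each repeat).
    """
    if pooling not in ("pooled", "per_fold"):
        raise ValueError("pooling must be 'pooled' or 'per_fold'")
    A = dataset.association
    never_pos = A.values == 0
    reports: list[MetricReport] = []
    repeat_rows: list[dict[str, float]] = []

    for r in range(n_repeats):
        foldspec = make_folds(A, scheme, n_folds, _repeat_seed(seed, r))
        pooled_scores, pooled_labels = [], []
        fold_reports: list[MetricReport] = []
        for f_idx, fold in enumerate(foldspec.folds):
            masked = mask_fold(A, fold)
            if scheme == "association_cv":
                assert (masked.values[fold[:, 0], fold[:, 1]] == 0).all(), "leakage: held-out cells not masked"
            else:
                assert (masked.values[:, fold] == 0).all(), "leakage: held-out drug columns not masked"
            F = predict(
                masked, dataset.drug_kernels, dataset.disease_kernels,
                drug_fusion=drug_fusion, disease_fusion=disease_fusion, params=params,
            )
            scores, labels = _fold_eval_sets(A, F, fold, scheme, never_pos)
            if pooling == "pooled":
                pooled_scores.append(scores)
                pooled_labels.append(labels)
            else:
                fold_reports.append(threshold_metrics(scores, labels, fold=str(f_idx), repeat=r))
        if pooling == "pooled":
            rep = threshold_metrics(
                np.concatenate(pooled_scores), np.concatenate(pooled_labels),
                fold="pooled", repeat=r,
            )
            reports.append(rep)
            repeat_rows.append(rep.as_dict())
        else:
            reports.extend(fold_reports)
            repeat_rows.append({
                k: float(np.mean([fr.as_dict()[k] for fr in fold_reports]))
                for k in fold_reports[0].as_dict()
            })

    summary = {
        k: (float(np.mean([row[k] for row in repeat_rows])),
            float(np.std([row[k] for row in repeat_rows])))
        for k in repeat_rows[0]
    }
    logger.info(
        "%s: %d folds x %d repeats -> AUROC %.4f +/- %.4f, AUPR %.4f +/- %.4f",
        scheme, n_folds, n_repeats, *summary["auroc"], *summary["aupr"],
    )
    return CVResult(reports=reports, summary=summary, scheme=scheme,
                    n_folds=n_folds, n_repeats=n_repeats)


def top_k_candidates(F: PredictionMatrix, A_known: AssociationMatrix,
                     axis: str, entity_id: str, k: int) -> list[tuple[str, float]]:
    """Top-k unknown partners of one entity by descending score.

    ``axis="drug"`` ranks candidate diseases for a drug; ``axis="disease"``
    ranks candidate drugs for a disease.  Pairs already known in
    ``A_known`` are excluded; ties are broken by ascending partner ID.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if F.disease_ids != A_known.disease_ids or F.drug_ids != A_known.drug_ids:
        raise ValueError("prediction and association matrices have mismatched axes")
    if axis == "drug":
        if entity_id not in F.drug_ids:
            raise KeyError(f"unknown drug {entity_id!r}")
        j = F.drug_ids.index(entity_id)
        scores, known, partners = F.scores[:, j], A_known.values[:, j], F.disease_ids
    elif axis == "disease":
        if entity_id not in F.disease_ids:
            raise KeyError(f"unknown disease {entity_id!r}")
        i = F.disease_ids.index(entity_id)
        scores, known, partners = F.scores[i, :], A_known.values[i, :], F.drug_ids
    else:
        raise ValueError(f"axis must be 'drug' or 'disease', got {axis!r}")
    candidates = [(partners[t], float(scores[t])) for t in range(len(partners)) if known[t] == 0]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return candidates[:k]


def orphan_predict(
    dataset: Dataset,
    drug_id: str,
    params: LapRLSParams | None = None,
    k: int = 20,
    *,
    drug_fusion: FusionParams | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate diseases for a drug treated as an orphan.

    The drug's entire association column is removed before the GIP kernels
    are recomputed, and the disease similarities are excluded from the
    model (lam forced to 0: drug subspace only), emulating a drug with no
    known indications.
    """
    A = dataset.association
    if drug_id not in A.drug_ids:
        raise KeyError(f"unknown drug {drug_id!r}")
    j = A.drug_ids.index(drug_id)
    A0 = A.copy()
    A0.values[:, j] = 0
    base = params or LapRLSParams()
    orphan_params = LapRLSParams(beta=base.beta, lam=0.0, jitter=base.jitter)
    F = predict(A0, dataset.drug_kernels, (), drug_fusion=drug_fusion, params=orphan_params)
    return top_k_candidates(F, A0, axis="drug", entity_id=drug_id, k=k)
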