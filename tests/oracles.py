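"""Independent brute-force oracles used by the test suite.

Each oracle is a literal, loop-based transcription of the operation it
checks, kept deliberately naive and separate from the vectorized package
code so that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "jaccard_brute",
    "skf_one_step",
    "laprls_normal_equations",
    "auroc_pair_counting",
    "aupr_brute",
    "exhaustive_threshold_metrics",
]


def jaccard_brute(profiles: np.ndarray) -> np.ndarray:
    """Set-based Jaccard over every pair of binary profile rows."""
    n = profiles.shape[0]
    sets = [set(np.flatnonzero(profiles[i]).tolist()) for i in range(n)]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = sets[i] | sets[j]
            K[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return K


def skf_one_step(mats: list[np.ndarray], k: int, alpha: float) -> np.ndarray:
    """One round of similarity kernel fusion, written out term by term.

    Column normalization, kNN-restricted row normalization, a single
    cross-diffusion update with the 1/(m-1) average over the other kernels
    (each updated kernel symmetrized), the m-way average, the kNN consensus
    weights, and the final elementwise weighting (symmetrized).
    """
    m, n = len(mats), mats[0].shape[0]

    thetas0 = []
    for M in mats:
        th = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                th[i, j] = M[i, j] / sum(M[v, j] for v in range(n))
        thetas0.append(th)

    indicators, phis = [], []
    for M in mats:
        ind = np.zeros((n, n))
        for i in range(n):
            order = sorted(range(n), key=lambda j: (-M[i, j], j))
            for j in order[:k]:
                ind[i, j] = 1.0
        ph = np.zeros((n, n))
        for i in range(n):
            denom = sum(M[i, v] * ind[i, v] for v in range(n))
            for j in range(n):
                ph[i, j] = M[i, j] * ind[i, j] / denom
        indicators.append(ind)
        phis.append(ph)

    thetas1 = []
    for u in range(m):
        others = sum(thetas0[r] for r in range(m) if r != u) / (m - 1)
        T = alpha * (phis[u] @ others @ phis[u].T) + (1.0 - alpha) * others
        thetas1.append((T + T.T) / 2.0)

    theta = sum(thetas1) / m

    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            vals = [ind[i, j] for ind in indicators]
            if all(v == 1.0 for v in vals):
                W[i, j] = 1.0
            elif all(v == 0.0 for v in vals):
                W[i, j] = 0.0
            else:
                W[i, j] = 0.5

    S = theta * W
    return (S + S.T) / 2.0


def laprls_normal_equations(S: np.ndarray, L: np.ndarray, Y: np.ndarray, beta: float) -> np.ndarray:
    """Stationary point of ||Y - S c||_F^2 + beta tr(c^T S L S c).

    Setting the gradient to zero gives (S^2 + beta S L S) c = S Y; the
    prediction is F = S c.  Solved with a generic dense solver.
    """
    M = S @ S + beta * (S @ L @ S)
    c = np.linalg.solve(M, S @ Y)
    return S @ c


def auroc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney statistic by explicit enumeration of pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-interpolated PR area: walk distinct thresholds in descending
    order, count TP/FP at 'score >= threshold' by brute force."""
    n_pos = int(labels.sum())
    area, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= thr
        tp = int(((pred) & (labels == 1)).sum())
        fp = int(((pred) & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def exhaustive_threshold_metrics(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Evaluate every distinct score value as a threshold (predicted
    positive iff score strictly greater) and keep the F1 maximizer,
    breaking ties toward the larger threshold."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    best = None
    for thr in sorted(set(scores.tolist()), reverse=True):
        pred = scores > thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        sen = tp / n_pos
        pre = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
        denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
        mcc = (tp * tn - fp * fn) / denom if denom else 0.0
        row = dict(threshold=thr, sen=sen, spe=tn / n_neg, pre=pre,
                   acc=(tp + tn) / (n_pos + n_neg), f1=f1, mcc=mcc)
        if best is None or f1 > best["f1"]:
            best = row
    return best
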