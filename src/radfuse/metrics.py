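"""Classification metrics and paired nonparametric comparison.

AUC is computed from the Mann-Whitney rank statistic with midrank tie
correction (equivalent to the all-pairs comparison statistic). Accuracy,
sensitivity and specificity are evaluated at the 0.5 probability threshold
against a stated positive class.

``wilcoxon_paired`` implements the classic signed-rank test: zero
differences dropped, midranks on absolute differences, exact two-sided null
for n <= 25 (computed by convolution over rank sums, identical to
enumerating all 2^n sign assignments), normal approximation with tie
correction above that. All differences zero returns p = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve via the rank-sum (all-pairs) statistic."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_metrics(y_true, prob, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / sensitivity / specificity of thresholded probabilities."""
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(prob, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spe = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / len(y)
    return {"acc": acc, "sen": sen, "spe": spe}


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    wilcoxon_statistic: float
    p_value: float
    n_pairs: int


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for W+ given the (mid)ranks of |differences|.

    Convolves the distribution of the positive-rank sum over all 2^n
    equally likely sign assignments. Midranks are multiples of 0.5, so
    doubling makes every rank an integer and the convolution exact.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(w_plus * 2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(a, b, name_a: str = "a", name_b: str = "b") -> ComparisonResult:
    """Paired Wilcoxon signed-rank test of two matched metric sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired sequences must be equal-length 1D arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return ComparisonResult(name_a, name_b, 0.0, 1.0, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance of the rank sum
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(name_a, name_b, w_plus, min(p, 1.0), n)
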