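"""Outcome prediction: per-type score rescaling, ROC analysis and
rank-test significance of the ROC area.

The ROC area is computed in its rank form: U counts, over all
(positive, negative) lesion pairs, the pairs where the positive scores
higher (ties count 1/2), and AUC = U / (n_pos * n_neg).  This identity
with the Mann-Whitney U statistic is also what provides the p-value for
the AUC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .normalization import LesionScoreRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ROCAnalysis",
    "rescale_by_type",
    "rescale_scores_by_type",
    "roc_curve",
    "roc_auc",
    "optimal_operating_point",
    "auc_significance",
    "analyze_roc",
]


@dataclass
class ROCAnalysis:
    """ROC curve plus area, operating point and significance."""

    thresholds: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0
    auc: float = float("nan")
    U: float = float("nan")
    p_value: float = float("nan")
    optimal_threshold: float = float("nan")
    tpr_opt: float = float("nan")
    fpr_opt: float = float("nan")
    ppv_opt: float = float("nan")


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def rescale_by_type(z: np.ndarray, types: np.ndarray) -> np.ndarray:
    """Min-max rescale z-scores to [0, 1] within each group.

    Groups of size 1, and degenerate groups where max == min, receive
    the neutral score 0.5 (logged).  This is the minimal reading of
    "rescaled to a prediction score ranging from 0 to 1"; it preserves
    the within-group ranking exactly.
    """
    z = np.asarray(z, dtype=float).ravel()
    types = np.asarray(types).ravel()
    if z.size == 0:
        raise ValueError("empty input")
    if z.size != types.size:
        raise ValueError("z and types differ in length")
    scores = np.empty_like(z)
    for t in np.unique(types):
        sel = types == t
        zt = z[sel]
        if zt.size == 1:
            logger.warning("group %r has a single lesion; prediction score set to 0.5", t)
            scores[sel] = 0.5
        elif zt.max() == zt.min():
            logger.warning("group %r has zero z-score spread; scores set to 0.5", t)
            scores[sel] = 0.5
        else:
            scores[sel] = (zt - zt.min()) / (zt.max() - zt.min())
    return scores


def rescale_scores_by_type(
    records: list[LesionScoreRecord],
) -> list[LesionScoreRecord]:
    """Return records with ``prediction_score`` filled in per primary type."""
    if not records:
        raise ValueError("empty input")
    z = np.array([r.z_lesion for r in records])
    types = np.array([r.primary_type for r in records])
    scores = rescale_by_type(z, types)
    return [replace(r, prediction_score=float(s)) for r, s in zip(records, scores)]


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCAnalysis:
    """ROC curve over all distinct score thresholds.

    Classification rule: predicted positive (progression) when
    score >= threshold; ties at the threshold count as positive.  The
    threshold sweep starts at a +inf sentinel so the curve begins at
    (0, 0) and ends at (1, 1).
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        tpr[i] = (pred & (labels == 1)).sum() / n_pos
        fpr[i] = (pred & (labels == 0)).sum() / n_neg
    return ROCAnalysis(thresholds=thresholds, fpr=fpr, tpr=tpr,
                       n_pos=n_pos, n_neg=n_neg)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """ROC area via the pairwise rank (Mann-Whitney U) form.

    Returns ``(auc, U)`` where U sums 1 for each (positive, negative)
    pair with score_pos > score_neg and 1/2 for each tied pair.  Equals
    the trapezoidal area under :func:`roc_curve`.
    """
    scores, labels = _check_binary(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    U = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    auc = U / (pos.size * neg.size)
    return auc, U


def optimal_operating_point(
    roc: ROCAnalysis, scores: np.ndarray, labels: np.ndarray
) -> ROCAnalysis:
    """Youden-optimal operating point and its positive predictive value.

    The optimal threshold maximizes J = tpr - fpr; ties are broken
    toward the higher threshold (fewer predicted positives).
    """
    scores, labels = _check_binary(scores, labels)
    J = roc.tpr - roc.fpr
    i = int(np.argmax(J))  # thresholds are descending: first max = highest thr
    thr = float(roc.thresholds[i])
    pred = scores >= thr
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    if tp + fp == 0:
        logger.warning("no predicted positives at the optimal threshold; PPV undefined")
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    return replace(
        roc,
        optimal_threshold=thr,
        tpr_opt=float(roc.tpr[i]),
        fpr_opt=float(roc.fpr[i]),
        ppv_opt=float(ppv),
    )


def auc_significance(
    U: float,
    n_pos: int,
    n_neg: int,
    alternative: str = "greater",
    method: str = "normal",
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    mid_p: bool = False,
) -> float:
    """p-value for H0: AUC = 1/2 via the Mann-Whitney U equivalence.

    ``method="normal"`` uses the large-sample normal approximation

        z = (U - n_pos n_neg / 2) / sqrt(n_pos n_neg (n_pos + n_neg + 1) / 12)

    without continuity correction (this approximates the mid-p exact
    tail; for balanced small cohorts the two agree to ~0.01).

    ``method="exact"`` enumerates all label assignments of the observed
    scores (requires ``scores`` and ``labels``; feasible for small
    cohorts) and reports the inclusive tail probability of U, or the
    mid-p tail (half weight on P(U = u)) when ``mid_p`` is set.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one member of each class")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if method == "normal":
        mean = n_pos * n_neg / 2.0
        sd = np.sqrt(n_pos * n_neg * (n_pos + n_neg + 1) / 12.0)
        zstat = (U - mean) / sd
        p = float(sps.norm.sf(zstat))
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(zstat)))
        return min(p, 1.0)
    if method == "exact":
        if scores is None or labels is None:
            raise ValueError("exact method needs scores and labels")
        scores, labels = _check_binary(scores, labels)
        n = scores.size
        stats = []
        for pos_idx in itertools.combinations(range(n), n_pos):
            lab = np.zeros(n, dtype=int)
            lab[list(pos_idx)] = 1
            _, u = roc_auc(scores, lab)
            stats.append(u)
        stats = np.asarray(stats)
        if alternative == "greater":
            if mid_p:
                p = float((stats > U + 1e-12).mean()
                          + 0.5 * (np.abs(stats - U) <= 1e-12).mean())
            else:
                p = float((stats >= U - 1e-12).mean())
        else:
            center = n_pos * n_neg / 2.0
            p = float((np.abs(stats - center) >= abs(U - center) - 1e-12).mean())
        return p
    raise ValueError(f"unknown method {method!r}")


def analyze_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    alternative: str = "greater",
    method: str = "normal",
) -> ROCAnalysis:
    """Full ROC analysis: curve, AUC/U, Youden point, PPV and p-value."""
    roc = roc_curve(scores, labels)
    auc, U = roc_auc(scores, labels)
    roc = replace(roc, auc=auc, U=U)
    roc = optimal_operating_point(roc, scores, labels)
    roc.p_value = auc_significance(
        U, roc.n_pos, roc.n_neg, alternative=alternative, method=method,
        scores=scores, labels=labels,
    )
    return roc
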