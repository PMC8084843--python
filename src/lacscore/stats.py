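"""Cohort-level statistics: rank concordance and one-way ANOVA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["ConcordanceResult", "AnovaResult", "kendalls_w", "oneway_anova"]


@dataclass(frozen=True)
class ConcordanceResult:
    W: float
    m: int  # raters (subjects)
    n: int  # items (regions)
    tie_corrected: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def kendalls_w(scores: np.ndarray) -> ConcordanceResult:
    """Kendall's coefficient of concordance across raters.

    ``scores`` is an (m raters) x (n items) matrix.  Each rater's items
    are ranked with mid-ranks for ties, and

        W = 12 S / (m^2 (n^3 - n) - m * sum_T)

    where S is the sum of squared deviations of item rank-sums from
    their mean and sum_T the usual tie correction
    sum over raters of sum over tie groups of (t^3 - t).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D raters x items matrix")
    m, n = scores.shape
    if m < 2:
        raise ValueError("concordance is undefined for fewer than 2 raters")
    if n < 2:
        raise ValueError("concordance needs at least 2 items")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain missing/non-finite entries")

    ranks = np.apply_along_axis(sps.rankdata, 1, scores)  # mid-ranks
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    sum_T = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        sum_T += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * sum_T
    if denom <= 0:
        raise ValueError("degenerate ranking: all items tied for every rater")
    W = 12.0 * S / denom
    return ConcordanceResult(W=float(W), m=m, n=n, tie_corrected=sum_T > 0)


def oneway_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA from between/within sums of squares.

    Singleton groups are allowed (they contribute to the between-group
    sum of squares only).  The p-value is the upper tail of the F
    distribution with (k-1, N-k) degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if not any(g.size >= 2 for g in groups):
        raise ValueError("at least one group must have >= 2 members")
    allx = np.concatenate(groups)
    if np.unique(allx).size == 1:
        raise ValueError("all observations identical: F undefined")

    k = len(groups)
    N = allx.size
    grand = allx.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between = k - 1
    df_within = N - k
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    if ss_within == 0.0:
        logger.warning("zero within-group variance: F reported as infinite")
        return AnovaResult(F=float("inf"), df_between=df_between,
                           df_within=df_within, p=0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)
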