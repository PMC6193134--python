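"""Comparative statistics: pairwise rank-sum tests and Kendall correlation.

Practice-level diversity values are compared between species with pairwise
two-sided Wilcoxon rank-sum tests under Bonferroni correction; associations
between practice metrics (e.g. diversity vs contributed consultations) use
Kendall's tau-b with a t-approximation for the null test.  Practice-level
diversity contains many exact ties (whole groups of practices at PD = 0),
so small samples are tested by exact permutation enumeration of the
rank-sum statistic and larger ones by the tie-corrected normal
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedResultError, ValidationError

logger = logging.getLogger(__name__)

#: largest pooled sample for which the exact permutation null is enumerated
EXACT_LIMIT = 10


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float  # rank sum of group A
    raw_p: float
    adj_p: float
    significant: bool


@dataclass
class CorrelationResult:
    tau: float
    p_value: float
    n: int


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Pooled samples up to :data:`EXACT_LIMIT` observations are tested by
    exhaustive enumeration of all rank assignments (midranks under ties);
    the two-sided p is twice the smaller tail, capped at 1.  Larger samples
    use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    nx_, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[:nx_].sum())
    if n <= EXACT_LIMIT:
        sums = np.array(
            [sum(c) for c in combinations(ranks, nx_)], dtype=float
        )
        eps = 1e-9
        p_le = np.mean(sums <= w_obs + eps)
        p_ge = np.mean(sums >= w_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_obs, float(p)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def pairwise_wilcoxon(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[ComparisonResult]:
    """All unordered pairwise rank-sum tests with Bonferroni correction.

    NaN values (undefined diversity) are dropped listwise per group before
    testing; ``adj_p = min(1, raw_p * n_pairs)``.
    """
    cleaned: dict[str, np.ndarray] = {}
    for name, vals in samples.items():
        arr = np.asarray(list(vals), dtype=float)
        n_dropped = int(np.isnan(arr).sum())
        if n_dropped:
            logger.info("group %r: dropped %d undefined values", name, n_dropped)
        arr = arr[~np.isnan(arr)]
        if len(arr) == 0:
            raise ValidationError(f"group {name!r} has no defined values")
        cleaned[name] = arr
    if len(cleaned) < 2:
        raise ValidationError("need at least two groups")

    pairs = list(combinations(sorted(cleaned), 2))
    results = []
    for a, b in pairs:
        w, raw_p = wilcoxon_ranksum(cleaned[a], cleaned[b])
        adj_p = min(1.0, raw_p * len(pairs))
        results.append(
            ComparisonResult(
                group_a=a, group_b=b, statistic=w, raw_p=raw_p,
                adj_p=adj_p, significant=adj_p < alpha,
            )
        )
    return results


def kendall_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Kendall's tau-b with a t-approximation p-value.

    Pairs with a NaN in either coordinate are dropped; needs >= 3 complete
    pairs and non-constant inputs.  The null test uses
    ``t = tau * sqrt((n - 2) / (1 - tau^2))`` on n - 2 degrees of freedom;
    perfect (anti)concordance reports p = 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must be the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d incomplete pairs", n_dropped)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedResultError("tau undefined for constant input")
    tau = float(sps.kendalltau(x, y, variant="b").statistic)
    if 1.0 - tau * tau <= 0.0:
        p = 0.0
    else:
        t = tau * np.sqrt((n - 2) / (1.0 - tau * tau))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(tau=tau, p_value=p, n=n)
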