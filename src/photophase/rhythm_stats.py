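"""Nonparametric testing for small-n expression time courses.

Two batteries, matched to small per-time-point sample sizes (n = 3–5):

* per condition, a Kruskal–Wallis test across time points followed by Dunn
  pairwise z-tests with Bonferroni adjustment — "is there any time-of-day
  variation, and between which time points?";
* per condition pair, a two-sided Mann–Whitney U test on the pooled
  replicate levels — "does the average expression differ between light
  conditions?" — with Shapiro–Wilk normality p-values reported per pool as
  the motivation for the nonparametric choice.

All tests are rank-based and therefore invariant under monotone increasing
transforms of the levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import ExpressionSeries

__all__ = [
    "TimepointTestResult",
    "ConditionComparisonResult",
    "InsufficientDataError",
    "dunn_bonferroni",
    "timepoint_test",
    "averaged_level_test",
]


class InsufficientDataError(ValueError):
    """Too few time points or replicates for the requested test."""


@dataclass
class TimepointTestResult:
    """Kruskal–Wallis across time points plus Dunn-Bonferroni post-hoc."""

    gene: str
    condition: str
    kw_statistic: float
    kw_p: float
    posthoc: pd.DataFrame  # symmetric matrix of adjusted p, unit diagonal
    degenerate: bool = False


@dataclass
class ConditionComparisonResult:
    """Mann–Whitney U comparison of averaged levels between two conditions."""

    gene: str
    pair: tuple[str, str]
    shapiro_p: tuple[float, float]
    mw_u: float
    mw_p: float
    significant: bool
    direction: str | None  # condition label with the higher average, or None
    method: str = "auto"


def dunn_bonferroni(
    groups: list[np.ndarray], labels: list | None = None
) -> pd.DataFrame:
    """Dunn pairwise z-tests on joint ranks, Bonferroni-adjusted.

    Uses midranks with the standard tie correction of the rank variance.
    Returns a symmetric matrix of adjusted p-values with unit diagonal.
    """
    if labels is None:
        labels = list(range(len(groups)))
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    k = len(groups)
    m_comparisons = k * (k - 1) // 2
    mat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p_adj = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_adj = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * m_comparisons)
        mat.iloc[i, j] = mat.iloc[j, i] = p_adj
    return mat


def timepoint_test(series: ExpressionSeries) -> TimepointTestResult:
    """Kruskal–Wallis across time points, Dunn-Bonferroni over all pairs.

    Requires at least three time points with two or more replicates each.
    All-tied data yields the degenerate result H = 0, p = 1.
    """
    times = np.unique(series.time)
    groups = [series.level[series.time == t] for t in times]
    if len(groups) < 3 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError(
            f"{series.gene}/{series.condition}: need >=3 time points with "
            f">=2 replicates each"
        )
    if np.all(series.level == series.level[0]):
        k = len(groups)
        posthoc = pd.DataFrame(np.ones((k, k)), index=times, columns=times)
        return TimepointTestResult(series.gene, series.condition,
                                   0.0, 1.0, posthoc, degenerate=True)
    h_stat, p = stats.kruskal(*groups)
    posthoc = dunn_bonferroni(groups, labels=list(times))
    return TimepointTestResult(series.gene, series.condition,
                               float(h_stat), float(p), posthoc)


def _pool(series: ExpressionSeries, aggregate: str) -> np.ndarray:
    if aggregate == "pool":
        return series.level
    if aggregate == "timepoint_mean":
        times = np.unique(series.time)
        return np.array([series.level[series.time == t].mean() for t in times])
    raise ValueError(f"unknown aggregate {aggregate!r}")


def averaged_level_test(
    series_a: ExpressionSeries,
    series_b: ExpressionSeries,
    alpha: float = 0.05,
    aggregate: str = "pool",
) -> ConditionComparisonResult:
    """Two-sided Mann–Whitney U on the pooled levels of two conditions.

    ``aggregate="pool"`` (default) pools every replicate observation;
    ``"timepoint_mean"`` first averages replicates within each time point.
    The exact null distribution is used when both pools have at most 20
    observations and the data contain no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a, b = _pool(series_a, aggregate), _pool(series_b, aggregate)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"{series_a.gene}: pools of {len(a)} and {len(b)} are too small"
        )

    def shapiro_p(x: np.ndarray) -> float:
        if np.all(x == x[0]):
            return np.nan
        return float(stats.shapiro(x).pvalue)

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_a == mean_b:
        direction = None
    else:
        direction = series_a.condition if mean_a > mean_b else series_b.condition
    return ConditionComparisonResult(
        gene=series_a.gene,
        pair=(series_a.condition, series_b.condition),
        shapiro_p=(shapiro_p(a), shapiro_p(b)),
        mw_u=float(res.statistic),
        mw_p=p,
        significant=p < alpha,
        direction=direction,
        method=method,
    )
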