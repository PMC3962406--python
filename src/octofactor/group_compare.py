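"""One-way ANOVA across observations and Tukey-Kramer pairwise comparison.

Each observation column of the expression matrix is treated as a group of
protein-level log2 ratios, and proteins within a group as independent
replicates. The F test asks whether the average protein expression change is
equal across the observations; when it is rejected, the Tukey-Kramer procedure
(studentized-range based, valid for unequal group sizes) locates the pairs of
observations whose mean log2 ratios differ at the family level.

Cells that were imputed in :func:`~octofactor.multivariate.build_matrix` are
excluded here rather than treated as data — imputation is a clustering
convention, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import ContractError
from .multivariate import ExpressionMatrix

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "observation_anova",
    "tukey_kramer",
]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]


@dataclass
class PairwiseComparison:
    obs_pair: tuple[str, str]
    mean_difference: float
    ci_low: float
    ci_high: float
    significant: bool


def _groups(matrix: ExpressionMatrix, include_imputed: bool) -> dict[str, np.ndarray]:
    groups = {}
    for obs in matrix.observation_keys:
        values = matrix.column(obs) if include_imputed else matrix.observed(obs)
        if len(values) < 2:
            raise ContractError(f"observation {obs!r} has fewer than 2 values")
        groups[obs] = np.asarray(values, dtype=float)
    if len(groups) < 2:
        raise ContractError("need at least 2 observations")
    return groups


def observation_anova(
    matrix: ExpressionMatrix, include_imputed: bool = False
) -> AnovaResult:
    """One-way fixed-effects ANOVA over observation columns.

    Missing (imputed) cells are excluded by default, so group sizes may differ.
    Degenerate case: when every group is identical the F statistic is 0 and the
    p-value 1 (the null is exactly true).
    """
    groups = _groups(matrix, include_imputed)
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:  # all data constant: null exactly true
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=k - 1,
        df_within=n_total - k,
        group_means={obs: float(a.mean()) for obs, a in groups.items()},
    )


def tukey_kramer(
    matrix: ExpressionMatrix,
    family_alpha: float = 0.05,
    include_imputed: bool = False,
) -> list[PairwiseComparison]:
    """All-pairs comparison of observation means with Tukey-Kramer correction.

    Confidence interval half-width for pair (i, j) is
    q_{α,k,df}/√2 · √(MS_within · (1/n_i + 1/n_j)); a pair is significant at the
    family level exactly when its interval excludes 0.
    """
    if not (0.0 < family_alpha < 1.0):
        raise ContractError("family_alpha must lie in (0, 1)")
    groups = _groups(matrix, include_imputed)
    keys = list(groups)
    arrays = [groups[k] for k in keys]
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_within = int(ns.sum()) - k
    ms_within = sum((n - 1) * a.var(ddof=1) for n, a in zip(ns, arrays)) / df_within
    q_crit = _studentized_range_crit(family_alpha, k, df_within)
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            half = q_crit / np.sqrt(2.0) * np.sqrt(
                ms_within * (1.0 / ns[i] + 1.0 / ns[j])
            )
            lo, hi = diff - half, diff + half
            comparisons.append(
                PairwiseComparison(
                    obs_pair=(keys[i], keys[j]),
                    mean_difference=diff,
                    ci_low=float(lo),
                    ci_high=float(hi),
                    significant=not (lo <= 0.0 <= hi),
                )
            )
    return comparisons


@lru_cache(maxsize=256)
def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range, computed numerically."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))
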