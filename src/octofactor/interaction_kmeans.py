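"""K-means on the equal-expression-deviation distance: knockout x ethanol interaction.

For each protein, take its log2 ratio E_a in the ethanol-only observation
(116:114) and E_b in the knockout+ethanol observation (121:114). If the
knockout had no effect on top of ethanol, the point (E_a, E_b) would sit on the
identity line E_a = E_b. The analysis therefore clusters proteins by their
perpendicular deviation from that line,

    D = |E_a - E_b| / sqrt(2),

with one-dimensional K-means (k = 3 by default); clusters are numbered by
ascending centroid, so cluster 1 hugs the expectation line and cluster k is
farthest from it. Because D depends only on |E_a - E_b|, any positive rescaling
of the distance yields identical clusters, and a point and its mirror image
across the identity line always share a cluster.

Points below the line (E_a > E_b, the "lower right" section of the scatter)
are proteins whose ethanol response is blunted or reversed by the knockout;
points above it ("upper left") are amplified by the knockout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_tables import QuantTable

__all__ = [
    "DeviationPoint",
    "KmeansResult",
    "equal_expression_distance",
    "classify_section",
    "deviation_points",
    "kmean_deviation",
    "section_cluster_crosstab",
    "cluster_report",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class DeviationPoint:
    """A protein's position relative to the equal-expression line."""

    protein_id: str
    e_a: float
    e_b: float
    distance: float = None  # type: ignore[assignment]
    section: str = None  # type: ignore[assignment]
    cluster: int | None = None

    def __post_init__(self) -> None:
        if self.distance is None:
            self.distance = equal_expression_distance(self.e_a, self.e_b)
        if self.section is None:
            self.section = classify_section(self.e_a, self.e_b)


def equal_expression_distance(e_a: float, e_b: float) -> float:
    """Perpendicular distance of (e_a, e_b) from the identity line, |e_a - e_b|/√2."""
    if not (math.isfinite(e_a) and math.isfinite(e_b)):
        raise ContractError("equal_expression_distance requires finite inputs")
    return abs(e_a - e_b) / SQRT2


def classify_section(e_a: float, e_b: float) -> str:
    """Scatter-plot section: 'lower_right' (e_a > e_b), 'upper_left' (e_a < e_b) or 'on_line'."""
    if e_a > e_b:
        return "lower_right"
    if e_a < e_b:
        return "upper_left"
    return "on_line"


def deviation_points(
    table: QuantTable, obs_a: str = "116:114", obs_b: str = "121:114"
) -> list[DeviationPoint]:
    """Build deviation points for every protein with both ratios recorded."""
    for obs in (obs_a, obs_b):
        if obs not in table.observations:
            raise ContractError(f"observation {obs!r} not in table")
    points = []
    for rec in table.proteins:
        e_a, e_b = rec.log2_ratio(obs_a), rec.log2_ratio(obs_b)
        if e_a is None or e_b is None:
            continue
        points.append(DeviationPoint(rec.accession, e_a, e_b))
    return points


@dataclass
class KmeansResult:
    points: list[DeviationPoint]  # cluster labels filled in, input order preserved
    centroids: np.ndarray  # ascending
    inertia: float  # within-cluster sum of squared distances

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {c: 0 for c in range(1, len(self.centroids) + 1)}
        for p in self.points:
            sizes[p.cluster] += 1
        return sizes


def _exact_1d_kmeans(values: np.ndarray, k: int):
    """Global minimiser of the K-means objective for scalar data.

    The optimal 1-D partition is contiguous in sorted order, so dynamic
    programming over prefix cut points finds the exact optimum in O(k n²)
    (vectorised over candidate cuts). Returns (labels, centroids, inertia)
    with clusters numbered 0..k-1 in ascending value order.
    """
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def interval_cost(a: np.ndarray, i: int) -> np.ndarray:
        """Within-cluster sum of squares of x[a:i] for a vector of starts a."""
        m = i - a
        s = ps[i] - ps[a]
        return ps2[i] - ps2[a] - s * s / m

    dp = np.full((k + 1, n + 1), math.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            starts = np.arange(j - 1, i)
            costs = dp[j - 1, starts] + interval_cost(starts, i)
            best = int(np.argmin(costs))
            dp[j, i] = costs[best]
            cut[j, i] = starts[best]

    bounds = [n]
    for j in range(k, 0, -1):
        bounds.append(int(cut[j, bounds[-1]]))
    bounds.reverse()
    labels_sorted = np.empty(n, dtype=int)
    for c, (a, b) in enumerate(zip(bounds, bounds[1:])):
        labels_sorted[a:b] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centroids = np.array([x[a:b].mean() for a, b in zip(bounds, bounds[1:])])
    return labels, centroids, float(dp[k, n])


def kmean_deviation(
    points: list[DeviationPoint],
    k: int = 3,
    restarts: int = 0,
    seed: int = 0,
) -> KmeansResult:
    """One-dimensional K-means on the equal-expression deviation distances.

    Because the distance is scalar, the K-means objective is solved exactly by
    dynamic programming over contiguous partitions of the sorted values — the
    result is the global optimum and fully deterministic, so ``restarts`` and
    ``seed`` are accepted for interface stability but unused. Clusters are
    renumbered by ascending centroid: label 1 = nearest the expectation line,
    label k = the farthest band.
    """
    del restarts, seed  # exact solver: no randomness to configure
    values = np.array([p.distance for p in points], dtype=float)
    n_distinct = len(np.unique(values))
    if k > n_distinct:
        raise ContractError(
            f"k={k} exceeds the {n_distinct} distinct distance values"
        )
    labels, centroids, inertia = _exact_1d_kmeans(values, k)
    for point, label in zip(points, labels):
        point.cluster = int(label) + 1
    return KmeansResult(points, centroids, inertia)


def section_cluster_crosstab(points: list[DeviationPoint]) -> pd.DataFrame:
    """Contingency counts of scatter section x cluster label.

    Rows are sections, columns cluster labels; margins are the section and
    cluster totals.
    """
    if any(p.cluster is None for p in points):
        raise ContractError("cluster labels not assigned; run kmean_deviation first")
    df = pd.DataFrame(
        {"section": [p.section for p in points], "cluster": [p.cluster for p in points]}
    )
    return pd.crosstab(df["section"], df["cluster"])


def cluster_report(points: list[DeviationPoint], min_cluster: int = 2) -> pd.DataFrame:
    """Report of proteins in clusters >= ``min_cluster``, grouped by section.

    Mirrors the published table layout: lower-right section first, then upper
    left, each sorted by e_a descending.
    """
    rows = [
        {
            "protein_id": p.protein_id,
            "e_a": p.e_a,
            "e_b": p.e_b,
            "distance": p.distance,
            "section": p.section,
            "cluster": p.cluster,
        }
        for p in points
        if p.cluster is not None and p.cluster >= min_cluster
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    section_order = {"lower_right": 0, "upper_left": 1, "on_line": 2}
    df["_s"] = df["section"].map(section_order)
    df = df.sort_values(["_s", "e_a"], ascending=[True, False]).drop(columns="_s")
    return df.reset_index(drop=True)
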