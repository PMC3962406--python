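"""Deviation distance, section rule and 1-D K-means vs the exhaustive optimum."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octofactor.errors import ContractError
from octofactor.interaction_kmeans import (
    DeviationPoint,
    classify_section,
    deviation_points,
    equal_expression_distance,
    kmean_deviation,
    section_cluster_crosstab,
)


def points_from(distances):
    """Points on the x-axis whose deviation distances equal the given values."""
    return [
        DeviationPoint(f"p{i}", d * math.sqrt(2.0), 0.0)
        for i, d in enumerate(distances)
    ]


class TestDistanceAndSection:
    def test_on_line_zero(self):
        assert equal_expression_distance(0.7, 0.7) == 0.0
        assert classify_section(0.5, 0.5) == "on_line"

    @pytest.mark.parametrize(
        "e_a,e_b,section",
        [
            (1.26, -4.29, "lower_right"),  # Cyp2e1
            (2.92, -0.31, "lower_right"),  # Gstm1
            (-2.91, 1.61, "upper_left"),  # Uqcrh
        ],
    )
    def test_worked_values(self, e_a, e_b, section):
        assert equal_expression_distance(e_a, e_b) == pytest.approx(
            abs(e_a - e_b) / math.sqrt(2.0)
        )
        assert classify_section(e_a, e_b) == section

    def test_non_finite_rejected(self):
        with pytest.raises(ContractError):
            equal_expression_distance(float("nan"), 0.0)

    def test_deviation_points_skip_missing(self, gender_table):
        # female-only proteins lack the male observation: no point is built
        points = deviation_points(gender_table, "116:114", "115:113")
        assert len(points) == 12  # proteins recorded in both columns


def exhaustive_best_partition(distances, k):
    """Minimal within-cluster sum of squares over contiguous partitions of the
    sorted values (the 1-D optimum is always contiguous)."""
    values = np.sort(np.asarray(distances, dtype=float))
    n = len(values)
    best = math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        wcss = sum(
            np.sum((values[a:b] - values[a:b].mean()) ** 2)
            for a, b in zip(bounds, bounds[1:])
        )
        best = min(best, wcss)
    return best


class TestKmeans:
    def test_perfectly_separated(self):
        points = points_from([0, 0, 0, 5, 5, 5, 10, 10, 10])
        result = kmean_deviation(points, k=3)
        labels = {p.protein_id: p.cluster for p in result.points}
        assert {labels[f"p{i}"] for i in range(3)} == {1}
        assert {labels[f"p{i}"] for i in range(3, 6)} == {2}
        assert {labels[f"p{i}"] for i in range(6, 9)} == {3}
        assert result.centroids == pytest.approx([0.0, 5.0, 10.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_contiguous_optimum(self, seed):
        rng = np.random.default_rng(seed)
        distances = rng.uniform(0, 4, size=rng.integers(6, 13))
        points = points_from(distances)
        result = kmean_deviation(points, k=3, restarts=10, seed=seed)
        assert result.inertia == pytest.approx(
            exhaustive_best_partition(distances, 3), rel=1e-9
        )

    def test_cluster_labels_ascend_with_centroid(self):
        points = points_from([3.0, 0.1, 1.4, 0.2, 2.9, 1.5])
        result = kmean_deviation(points, k=3)
        by_cluster = {}
        for p in result.points:
            by_cluster.setdefault(p.cluster, []).append(p.distance)
        assert max(by_cluster[1]) <= min(by_cluster[2])
        assert max(by_cluster[2]) <= min(by_cluster[3])

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0, 3, 20)
        for factor in (0.5, 3.0, 17.0):
            a = kmean_deviation(points_from(base), k=3, seed=0)
            b = kmean_deviation(points_from(base * factor), k=3, seed=0)
            assert [p.cluster for p in a.points] == [p.cluster for p in b.points]

    def test_reflection_shares_cluster(self):
        # a point and its mirror image across the identity line have the same
        # distance, so they always land in the same cluster
        pts = [DeviationPoint("a", 2.0, -1.0), DeviationPoint("b", -1.0, 2.0)] + [
            DeviationPoint(f"f{i}", x, 0.0) for i, x in enumerate((0.1, 0.2, 4.0, 4.1))
        ]
        result = kmean_deviation(pts, k=3, seed=1)
        labels = {p.protein_id: p.cluster for p in result.points}
        assert labels["a"] == labels["b"]

    def test_k_exceeding_distinct_values(self):
        with pytest.raises(ContractError):
            kmean_deviation(points_from([1.0, 1.0, 1.0]), k=2)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    distances=st.lists(
        st.floats(0, 10, allow_nan=False), min_size=8, max_size=15, unique=True
    )
)
def test_converged_solution_is_contiguous_optimum(distances):
    points = points_from(distances)
    result = kmean_deviation(points, k=3, restarts=15, seed=0)
    assert result.inertia <= exhaustive_best_partition(distances, 3) * (1 + 1e-9) + 1e-12


def test_crosstab_margins():
    rng = np.random.default_rng(2)
    pts = [
        DeviationPoint(f"p{i}", float(rng.normal()), float(rng.normal()))
        for i in range(30)
    ]
    kmean_deviation(pts, k=3, seed=0)
    table = section_cluster_crosstab(pts)
    assert int(table.to_numpy().sum()) == 30
    sections = {p.section for p in pts}
    assert set(table.index) == sections


def test_crosstab_requires_labels():
    with pytest.raises(ContractError):
        section_cluster_crosstab([DeviationPoint("p", 1.0, 0.0)])
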