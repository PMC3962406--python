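"""Activation z-score and hypergeometric overlap against enumeration oracles."""

import itertools
import math

import pytest

from octofactor import datasets
from octofactor.errors import ContractError
from octofactor.io_tables import RegulatorEdge, RegulatorNetwork
from octofactor.regulator_activation import (
    consistency_report,
    overlap_pvalue,
    score_regulators,
)


def network_of(regulator, signed_targets):
    return RegulatorNetwork(
        [RegulatorEdge(regulator, t, s) for t, s in signed_targets.items()]
    )


class TestActivationZ:
    def test_all_consistent(self):
        net = network_of("R", {f"t{i}": 1 for i in range(7)})
        directions = {f"t{i}": 1 for i in range(7)}
        (score,) = score_regulators(directions, net, background_size=100)
        assert score.n_consistent == 7 and score.n_inconsistent == 0
        assert score.z == pytest.approx(7 / math.sqrt(7))
        assert score.predicted_state == "activated"

    def test_balanced_targets_undetermined(self):
        net = network_of("R", {"a": 1, "b": 1, "c": -1, "d": -1})
        directions = {"a": 1, "b": -1, "c": -1, "d": 1}
        (score,) = score_regulators(directions, net, background_size=50)
        assert score.z == pytest.approx(0.0)
        assert score.predicted_state == "undetermined"

    def test_flip_negates_z(self):
        net = datasets.load_regulator_network()
        directions = datasets.load_regulator_directions("116:114")
        flipped = {g: -d for g, d in directions.items()}
        for fwd, rev in zip(
            score_regulators(directions, net, 863),
            score_regulators(flipped, net, 863),
        ):
            if fwd.z is None:
                assert rev.z is None
            else:
                assert rev.z == pytest.approx(-fwd.z)

    def test_z_bounded_by_sqrt_n(self):
        net = datasets.load_regulator_network()
        directions = datasets.load_regulator_directions("121:114")
        for score in score_regulators(directions, net, 863):
            if score.z is not None and score.n_targets_in_dataset:
                assert abs(score.z) <= math.sqrt(score.n_targets_in_dataset) + 1e-12

    def test_no_targets_in_dataset(self):
        net = network_of("R", {"absent": 1})
        (score,) = score_regulators({"other": 1}, net, background_size=10)
        assert score.n_targets_in_dataset == 0
        assert score.z is None
        assert score.overlap_p == 1.0

    def test_unsigned_edges_excluded_from_consistency(self):
        net = network_of("R", {"a": 1, "b": None})
        (score,) = score_regulators({"a": 1, "b": 1}, net, background_size=10)
        assert score.n_targets_in_dataset == 1  # only the signed edge counts
        assert score.n_overlap == 2  # but both drive the overlap


class TestOverlapP:
    def test_enumeration_oracle(self):
        background, targets, draws = 10, 4, 5
        population = [1] * targets + [0] * (background - targets)
        total = 0
        counts = {}
        for combo in itertools.combinations(range(background), draws):
            hits = sum(population[i] for i in combo)
            counts[hits] = counts.get(hits, 0) + 1
            total += 1
        for overlap in range(0, min(targets, draws) + 1):
            expected = sum(v for h, v in counts.items() if h >= overlap) / total
            assert overlap_pvalue(overlap, draws, targets, background) == pytest.approx(
                expected, rel=1e-10
            )

    def test_trivial_cases(self):
        assert overlap_pvalue(0, 5, 4, 10) == 1.0
        assert overlap_pvalue(6, 6, 6, 6) == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        values = [overlap_pvalue(k, 20, 30, 200) for k in range(0, 12)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bounds_enforced(self):
        with pytest.raises(ContractError):
            overlap_pvalue(5, 4, 10, 100)
        with pytest.raises(ContractError):
            overlap_pvalue(1, 5, 200, 100)


class TestConsistencyReport:
    def test_negative_edge_down_supports_activation(self):
        net = network_of("NRF2", {"Fabp1": -1})
        (score,) = score_regulators({"Fabp1": -1}, net, background_size=10)
        report = consistency_report(score, {"Fabp1": -1}, net)
        assert report.loc[0, "label"] == "consistent-with-activation"

    @pytest.mark.parametrize(
        "direction,label",
        [(1, "consistent-with-activation"), (-1, "consistent-with-inhibition")],
    )
    def test_single_positive_edge(self, direction, label):
        net = network_of("R", {"t": 1})
        (score,) = score_regulators({"t": direction}, net, background_size=5)
        report = consistency_report(score, {"t": direction}, net)
        assert report.loc[0, "label"] == label

    def test_empty_dataset(self):
        net = network_of("R", {"t": 1})
        (score,) = score_regulators({}, net, background_size=5)
        assert consistency_report(score, {}, net).empty
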