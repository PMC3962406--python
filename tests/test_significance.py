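"""Significance criteria, strict boundaries and gender overlap logic."""

import pytest
from hypothesis import given, settings, strategies as st

from octofactor.errors import ContractError, ValidationError
from octofactor.io_tables import ObservationRatio, ProteinRecord, QuantTable
from octofactor.significance import (
    SignificanceCriteria,
    changed_proteins,
    overlap_analysis,
    significant_proteins,
)


def table_from_rows(rows):
    """rows: {accession: (log2R, p)} on a single observation 116:114."""
    proteins = [
        ProteinRecord(
            accession=acc,
            ratios={"116:114": ObservationRatio("116", "114", v, p)},
        )
        for acc, (v, p) in rows.items()
    ]
    return QuantTable(proteins, ["116:114"])


def test_strict_boundaries_excluded():
    table = table_from_rows(
        {
            "at_fold": (1.0, 0.01),  # |log2R| equals the threshold
            "at_alpha": (1.5, 0.05),  # p equals alpha
            "passes": (1.5, 0.01),
            "missing": (None, None),
        }
    )
    result = significant_proteins(table, "116:114", SignificanceCriteria(require_p=True))
    assert result.table.accessions == ["passes"]
    assert (result.n_up, result.n_down) == (1, 0)


def test_missing_p_policy():
    table = table_from_rows({"no_p": (2.0, None)})
    lenient = significant_proteins(table, "116:114", SignificanceCriteria())
    strict = significant_proteins(
        table, "116:114", SignificanceCriteria(require_p=True)
    )
    assert lenient.n == 1 and strict.n == 0


def test_empty_table():
    result = significant_proteins(
        QuantTable([], ["116:114"]), "116:114", SignificanceCriteria()
    )
    assert result.n == 0 and result.n_up == 0 and result.n_down == 0


def test_unknown_observation_rejected():
    with pytest.raises(ContractError):
        significant_proteins(QuantTable([], ["116:114"]), "121:114")


def test_criteria_validation():
    with pytest.raises(ValidationError):
        SignificanceCriteria(min_abs_log2=-1)
    with pytest.raises(ValidationError):
        SignificanceCriteria(alpha=0.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    values=st.lists(
        st.tuples(
            st.floats(-4, 4, allow_nan=False), st.floats(0, 1, allow_nan=False)
        ),
        min_size=1,
        max_size=30,
    ),
    thresholds=st.tuples(st.floats(0, 3), st.floats(0.001, 0.2)),
)
def test_monotone_in_thresholds(values, thresholds):
    """Shrinking alpha or growing the fold threshold never enlarges the set."""
    table = table_from_rows({f"p{i}": vp for i, vp in enumerate(values)})
    base_fold, base_alpha = thresholds
    loose = significant_proteins(
        table, "116:114", SignificanceCriteria(base_fold, min(base_alpha * 2, 0.4))
    )
    tight = significant_proteins(
        table, "116:114", SignificanceCriteria(base_fold + 0.5, base_alpha)
    )
    assert set(tight.table.accessions) <= set(loose.table.accessions)


def test_changed_proteins_requires_recorded_p(interaction_table):
    # every fixture protein has p < 0.05 somewhere except Gm4952, whose best
    # printed p is exactly 0.050 — excluded by the strict inequality
    kept = changed_proteins(interaction_table, interaction_table.observations, 0.05)
    assert len(kept) == 44
    dropped = set(interaction_table.accessions) - set(kept.accessions)
    assert {interaction_table.get(a).gene_symbol for a in dropped} == {"Gm4952"}


def test_changed_proteins_alpha_zero_empty(interaction_table):
    assert len(changed_proteins(interaction_table, ["116:114"], 0.0)) == 0


def test_changed_proteins_needs_observations(interaction_table):
    with pytest.raises(ContractError):
        changed_proteins(interaction_table, [], 0.05)


def test_overlap_partition_sizes():
    rows = {
        "A": (2.0, 0.01),
        "B": (1.5, 0.01),
        "C": (-1.5, 0.01),
        "D": (1.2, 0.01),
    }
    table = table_from_rows(rows)
    set_a = table.subset(["A", "B", "C"])
    set_b = table.subset(["B", "C", "D"])
    report = overlap_analysis(set_a, set_b, "116:114", "116:114")
    assert report.shared == {"B", "C"}
    assert report.only_a == {"A"} and report.only_b == {"D"}
    assert len(report.shared) + len(report.only_a) == len(set_a)
    assert len(report.shared) + len(report.only_b) == len(set_b)
    assert report.opposite_direction == set()  # same observation twice


def test_overlap_same_set_twice():
    table = table_from_rows({"A": (2.0, 0.01), "B": (-1.5, 0.01)})
    report = overlap_analysis(table, table, "116:114", "116:114")
    assert report.shared == {"A", "B"}
    assert not report.only_a and not report.only_b
    assert report.opposite_direction == set()
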