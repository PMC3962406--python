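"""Significance filtering and male/female set comparison.

A protein counts as *significantly changed* in an observation when its ratio is
recorded, |log2 R| strictly exceeds the fold-change threshold (default 1, i.e. a
two-fold change) and the ratio-test p-value is strictly below alpha (default
0.05). Both inequalities are strict, so boundary values are excluded. Published
summary tables often print only the ratios of proteins that already passed the
p filter; for such tables no p is recorded and the p criterion is vacuous —
``require_p=True`` restores the strict behaviour of rejecting unrecorded p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, ValidationError
from .io_tables import QuantTable

__all__ = [
    "SignificanceCriteria",
    "FilterResult",
    "OverlapReport",
    "significant_proteins",
    "changed_proteins",
    "overlap_analysis",
]


@dataclass(frozen=True)
class SignificanceCriteria:
    """Thresholds defining a significantly changed protein."""

    min_abs_log2: float = 1.0  # |log2 R| must strictly exceed this
    alpha: float = 0.05  # ratio-test p must be strictly below this
    require_p: bool = False  # reject proteins without a recorded p-value

    def __post_init__(self) -> None:
        if self.min_abs_log2 < 0:
            raise ValidationError("min_abs_log2 must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")

    def passes(self, log2_ratio: float | None, p_value: float | None) -> bool:
        if log2_ratio is None:
            return False
        if abs(log2_ratio) <= self.min_abs_log2:
            return False
        if p_value is None:
            return not self.require_p
        return p_value < self.alpha


@dataclass
class FilterResult:
    """Subset of a quant table passing the significance criteria in one observation."""

    table: QuantTable
    observation: str
    n_up: int
    n_down: int

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class OverlapReport:
    """Partition of two significant sets into shared / unique accessions.

    ``opposite_direction`` holds the shared accessions whose log2 ratios have
    opposite signs in the two observations.
    """

    shared: set[str]
    only_a: set[str]
    only_b: set[str]
    opposite_direction: set[str]
    up_down: dict[str, tuple[int, int]] = field(default_factory=dict)


def significant_proteins(
    table: QuantTable,
    obs: str,
    criteria: SignificanceCriteria | None = None,
) -> FilterResult:
    """Proteins significantly changed in one observation, with up/down counts."""
    if obs not in table.observations:
        raise ContractError(f"observation {obs!r} not in table")
    criteria = criteria or SignificanceCriteria()
    keep: list[str] = []
    n_up = n_down = 0
    for rec in table.proteins:
        value = rec.log2_ratio(obs)
        if criteria.passes(value, rec.p_value(obs)):
            keep.append(rec.accession)
            if value > 0:
                n_up += 1
            else:
                n_down += 1
    return FilterResult(table.subset(keep), obs, n_up, n_down)


def changed_proteins(
    table: QuantTable,
    observations: list[str],
    alpha: float = 0.05,
) -> QuantTable:
    """Proteins with a ratio-test p strictly below alpha in at least one observation.

    This is the inclusive "expression changed" filter feeding PCA, ANOVA,
    hierarchical clustering and the interaction K-means; it imposes no fold-change
    threshold and requires a recorded p-value.
    """
    if not observations:
        raise ContractError("observations must be non-empty")
    for obs in observations:
        if obs not in table.observations:
            raise ContractError(f"observation {obs!r} not in table")
    keep = [
        rec.accession
        for rec in table.proteins
        if any(
            (p := rec.p_value(obs)) is not None and p < alpha for obs in observations
        )
    ]
    return table.subset(keep)


def overlap_analysis(
    set_a: QuantTable,
    set_b: QuantTable,
    obs_a: str,
    obs_b: str,
) -> OverlapReport:
    """Compare two significant sets drawn from the same parent table.

    Shared proteins are classified opposite-direction when
    sign(log2R in obs_a) * sign(log2R in obs_b) < 0.
    """
    acc_a, acc_b = set(set_a.accessions), set(set_b.accessions)
    shared = acc_a & acc_b
    only_a, only_b = acc_a - shared, acc_b - shared

    def _value(table: QuantTable, accession: str, obs: str) -> float:
        value = table.get(accession).log2_ratio(obs)
        if value is None:
            raise ValidationError(
                f"protein {accession} has no recorded ratio in {obs!r}"
            )
        return value

    opposite = {
        acc
        for acc in shared
        if _value(set_a, acc, obs_a) * _value(set_b, acc, obs_b) < 0
    }

    def _counts(table: QuantTable, accessions: set[str], obs: str) -> tuple[int, int]:
        ups = sum(1 for acc in accessions if _value(table, acc, obs) > 0)
        return ups, len(accessions) - ups

    up_down = {
        "shared_a": _counts(set_a, shared, obs_a),
        "shared_b": _counts(set_b, shared, obs_b),
        "only_a": _counts(set_a, only_a, obs_a),
        "only_b": _counts(set_b, only_b, obs_b),
    }
    return OverlapReport(shared, only_a, only_b, opposite, up_down)
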