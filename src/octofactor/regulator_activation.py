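"""Open upstream-regulator activation scoring on user-supplied signed networks.

Given a set of differentially expressed proteins and an edge list of known
regulator -> target relations (sign +1 = the active regulator up-regulates the
target, -1 = down-regulates), each regulator receives:

* an activation z-score, z = (n_consistent - n_inconsistent) / sqrt(N), where a
  target is *consistent* with regulator activation when its observed direction
  (the sign of its log2 ratio) equals the edge sign, and N = n_consistent +
  n_inconsistent. z >= +2 predicts the regulator activated, z <= -2 inhibited.
* an overlap p-value: the hypergeometric upper-tail probability of drawing at
  least the observed number of the regulator's targets when sampling the
  dataset from the quantified background.

This is the transparent, unweighted variant of the score popularised by causal
network analysis tools; commercial implementations add proprietary edge weights
and literature-bias corrections, so their printed z-scores are approximated
here, not reproduced. Targets with an unknown edge sign or without an observed
direction contribute to the overlap count but never to consistency counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import stats

from .errors import ContractError
from .io_tables import QuantTable, RegulatorNetwork

__all__ = [
    "RegulatorScore",
    "score_regulators",
    "score_regulators_from_table",
    "consistency_report",
    "overlap_pvalue",
    "directions_from_table",
]

ACTIVATION_THRESHOLD = 2.0


@dataclass
class RegulatorScore:
    regulator: str
    n_targets_in_dataset: int  # N: signed targets with an observed direction
    n_consistent: int
    n_inconsistent: int
    n_overlap: int  # all in-dataset targets, signed or not (drives overlap_p)
    z: float | None  # None when N = 0
    overlap_p: float
    predicted_state: str  # activated | inhibited | undetermined
    consistent_targets: list[str] = field(default_factory=list)
    inconsistent_targets: list[str] = field(default_factory=list)


def overlap_pvalue(
    overlap: int, dataset_size: int, regulator_targets: int, background_size: int
) -> float:
    """Hypergeometric upper tail P(X >= overlap).

    X counts the regulator's targets hit when ``dataset_size`` genes are drawn
    without replacement from a background of ``background_size`` genes of which
    ``regulator_targets`` are targets.
    """
    if not (0 <= overlap <= min(dataset_size, regulator_targets)):
        raise ContractError("overlap exceeds dataset or target count")
    if regulator_targets > background_size or dataset_size > background_size:
        raise ContractError("target or dataset count exceeds background size")
    if overlap == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(overlap - 1, background_size, regulator_targets, dataset_size)
    )


def directions_from_table(table: QuantTable, obs: str) -> dict[str, int]:
    """Gene symbol -> observed direction (sign of log2 ratio) for one observation.

    Genes with a missing ratio or an exactly-zero log2 ratio are omitted; where
    several proteins share a gene symbol the first nonzero direction wins.
    """
    if obs not in table.observations:
        raise ContractError(f"observation {obs!r} not in table")
    directions: dict[str, int] = {}
    for rec in table.proteins:
        gene = rec.gene_symbol
        if not gene or gene in directions:
            continue
        value = rec.log2_ratio(obs)
        if value is None or value == 0:
            continue
        directions[gene] = 1 if value > 0 else -1
    return directions


def score_regulators(
    directions: Mapping[str, int],
    network: RegulatorNetwork,
    background_size: int,
    dataset_size: int | None = None,
) -> list[RegulatorScore]:
    """Score every regulator in the network against observed target directions.

    ``directions`` maps gene symbols in the dataset to +1/-1.
    ``background_size`` is the number of quantified genes the dataset was drawn
    from; ``dataset_size`` defaults to ``len(directions)``. Gene matching is
    case-insensitive. A regulator with no in-dataset targets is reported with
    N = 0, z undefined (None) and overlap_p = 1.
    """
    dataset_size = len(directions) if dataset_size is None else dataset_size
    if background_size < dataset_size:
        raise ContractError("background_size must be at least the dataset size")
    folded = {gene.lower(): d for gene, d in directions.items()}
    scores = []
    for regulator in network.regulators:
        edges = network.targets_of(regulator)
        consistent, inconsistent = [], []
        n_overlap = 0
        for edge in edges:
            direction = folded.get(edge.target.lower())
            if direction is None:
                continue
            n_overlap += 1
            if edge.sign is None or direction == 0:
                continue
            if direction == edge.sign:
                consistent.append(edge.target)
            else:
                inconsistent.append(edge.target)
        n = len(consistent) + len(inconsistent)
        z = (len(consistent) - len(inconsistent)) / math.sqrt(n) if n > 0 else None
        if z is not None and z >= ACTIVATION_THRESHOLD:
            state = "activated"
        elif z is not None and z <= -ACTIVATION_THRESHOLD:
            state = "inhibited"
        else:
            state = "undetermined"
        p = overlap_pvalue(n_overlap, dataset_size, len(edges), background_size)
        scores.append(
            RegulatorScore(
                regulator=regulator,
                n_targets_in_dataset=n,
                n_consistent=len(consistent),
                n_inconsistent=len(inconsistent),
                n_overlap=n_overlap,
                z=z,
                overlap_p=p,
                predicted_state=state,
                consistent_targets=consistent,
                inconsistent_targets=inconsistent,
            )
        )
    return scores


def score_regulators_from_table(
    table: QuantTable,
    obs: str,
    network: RegulatorNetwork,
    background_size: int,
) -> list[RegulatorScore]:
    """Convenience wrapper deriving target directions from a filtered quant table."""
    return score_regulators(
        directions_from_table(table, obs), network, background_size
    )


def consistency_report(
    score: RegulatorScore,
    directions: Mapping[str, int],
    network: RegulatorNetwork,
) -> pd.DataFrame:
    """Per-target table for one regulator: direction, edge sign and consistency label.

    Labels: ``consistent-with-activation`` (direction equals edge sign),
    ``consistent-with-inhibition`` (direction opposite the edge sign — i.e. the
    observation supports the regulator being inhibited), or ``unsigned-edge``
    when the relation's direction is unknown.
    """
    folded = {gene.lower(): (gene, d) for gene, d in directions.items()}
    rows = []
    for edge in network.targets_of(score.regulator):
        hit = folded.get(edge.target.lower())
        if hit is None:
            continue
        _, direction = hit
        if edge.sign is None:
            label = "unsigned-edge"
        elif direction == edge.sign:
            label = "consistent-with-activation"
        else:
            label = "consistent-with-inhibition"
        rows.append(
            {
                "target": edge.target,
                "observed_direction": direction,
                "edge_sign": edge.sign,
                "label": label,
            }
        )
    return pd.DataFrame(rows, columns=["target", "observed_direction", "edge_sign", "label"])
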