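"""Loaders for the packaged fixture tables.

Three small TSVs transcribed from the published study ship with the package:

* ``ethanol_gender_table.tsv`` — 90 proteins significantly changed by ethanol
  in male (116:114) and/or female (115:113) wild-type mice. The published table
  prints log2 ratios only (its entries already passed the |log2 R| > 1, p < 0.05
  filter), so no p-value columns are present.
* ``interaction_cluster_table.tsv`` — the 45 proteins assigned to K-means
  clusters 2 and 3 in the ethanol (116:114) vs knockout+ethanol (121:114)
  comparison, with log2 ratios, p-values, and the published section / cluster
  labels carried as annotations.
* ``regulator_network.tsv`` — the 8 upstream regulators' target lists; edge
  signs are recorded only where the study states them (all NRF2 targets, and
  the 11 PPARα targets reported as consistent with PPARα inhibition); the rest
  are unknown (``?``).
* ``regulator_target_directions.tsv`` — observed up/down direction of each
  regulator target in the 116:114 and 121:114 datasets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io_tables import QuantTable, RegulatorNetwork, read_network, read_quant_table

__all__ = [
    "fixture_path",
    "load_gender_table",
    "load_interaction_table",
    "load_regulator_network",
    "load_regulator_directions",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(resources.files("octofactor").joinpath("data", name))


def load_gender_table() -> QuantTable:
    """90-protein male/female ethanol-response table (observations 116:114, 115:113)."""
    return read_quant_table(fixture_path("ethanol_gender_table.tsv"))


def load_interaction_table() -> QuantTable:
    """45-protein ethanol vs knockout+ethanol table with published cluster labels.

    The published section and cluster assignments are available per record as
    ``annotations["printed_section"]`` and ``annotations["printed_cluster"]``.
    """
    return read_quant_table(fixture_path("interaction_cluster_table.tsv"))


def load_regulator_network() -> RegulatorNetwork:
    """Upstream-regulator edge list for the 8 scored regulators."""
    return read_network(fixture_path("regulator_network.tsv"))


def load_regulator_directions(obs: str = "116:114") -> dict[str, int]:
    """Observed target directions (+1 up / -1 down) for one observation.

    Genes without a recorded direction in that observation are omitted.
    """
    df = pd.read_csv(fixture_path("regulator_target_directions.tsv"), sep="\t")
    if obs not in df.columns:
        raise KeyError(f"no direction column for observation {obs!r}")
    out: dict[str, int] = {}
    for gene, raw in zip(df["gene_symbol"], df[obs]):
        text = str(raw).strip()
        if text in {"-", "", "nan"}:
            continue
        out[str(gene)] = int(text)
    return out
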