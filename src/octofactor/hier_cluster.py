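"""Hierarchical clustering of observations on the normalised changed-protein matrix.

Observation columns are standardised (mean 0, sd 1 within each observation),
then clustered agglomeratively with Euclidean distance and complete linkage.
The two-way cut at the top split partitions the conditions into the two major
expression regimes; in the study design this separates the knockout conditions
from the wild-type ones when the knockout main effect dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ContractError
from .multivariate import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "normalize_within_observation",
    "cluster_observations",
    "cluster_proteins",
]


@dataclass
class Dendrogram:
    """Complete-linkage merge history over observation leaves.

    ``linkage_matrix`` is the standard 4-column agglomeration encoding
    (left, right, height, size); heights are non-decreasing under complete
    linkage. ``two_way_labels`` maps each observation to 1 or 2 per the cut at
    the top split.
    """

    linkage_matrix: np.ndarray
    leaves: list[str]  # observation keys, dendrogram leaf order
    observation_keys: list[str]  # input order
    two_way_labels: dict[str, int]

    def partition(self) -> tuple[set[str], set[str]]:
        """The two-way cut as a pair of observation sets."""
        a = {k for k, v in self.two_way_labels.items() if v == 1}
        b = {k for k, v in self.two_way_labels.items() if v == 2}
        return a, b


def normalize_within_observation(
    matrix: ExpressionMatrix, ddof: int = 1
) -> ExpressionMatrix:
    """Standardise each observation column to mean 0, sd 1.

    Sample (n-1) standard deviation by default; pass ``ddof=0`` for the
    population convention. Zero-spread columns are a contract error.
    """
    values = matrix.values.astype(float)
    sd = values.std(axis=0, ddof=ddof)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = [
            matrix.observation_keys[j]
            for j in range(values.shape[1])
            if not (np.isfinite(sd[j]) and sd[j] > 0)
        ]
        raise ContractError(f"zero-spread observation columns: {bad}")
    normalized = (values - values.mean(axis=0)) / sd
    return ExpressionMatrix(
        normalized,
        matrix.missing_mask.copy(),
        list(matrix.protein_ids),
        list(matrix.observation_keys),
    )


def cluster_observations(matrix: ExpressionMatrix) -> Dendrogram:
    """Complete-linkage Euclidean clustering of observation columns.

    Expects a fully imputed matrix (see
    :func:`~octofactor.multivariate.build_matrix`). Imputation happens before
    normalisation so imputed cells carry the no-change value, not a shifted one.
    """
    if len(matrix.observation_keys) < 2:
        raise ContractError("need at least 2 observations to cluster")
    columns = matrix.values.T  # observations as points in protein space
    z = linkage(pdist(columns, metric="euclidean"), method="complete")
    labels = fcluster(z, t=2, criterion="maxclust")
    leaf_order = [matrix.observation_keys[i] for i in leaves_list(z)]
    return Dendrogram(
        linkage_matrix=z,
        leaves=leaf_order,
        observation_keys=list(matrix.observation_keys),
        two_way_labels={
            key: int(label) for key, label in zip(matrix.observation_keys, labels)
        },
    )


def cluster_proteins(matrix: ExpressionMatrix) -> Dendrogram:
    """Row-side (protein) dendrogram for the heatmap, same metric and linkage.

    Provided for completeness of the two-way clustered display; only the
    observation-side dendrogram carries the analysis conclusions.
    """
    if len(matrix.protein_ids) < 2:
        raise ContractError("need at least 2 proteins to cluster")
    z = linkage(pdist(matrix.values, metric="euclidean"), method="complete")
    labels = fcluster(z, t=2, criterion="maxclust")
    leaf_order = [matrix.protein_ids[i] for i in leaves_list(z)]
    return Dendrogram(
        linkage_matrix=z,
        leaves=leaf_order,
        observation_keys=list(matrix.protein_ids),
        two_way_labels={
            pid: int(label) for pid, label in zip(matrix.protein_ids, labels)
        },
    )
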