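"""PCA over the changed-protein matrix and Hotelling T² ranking of extreme proteins.

Proteins are the PCA samples and observations the variables: each protein is a
point in the 7-dimensional space of condition log2 ratios, and the biplot
projects the 7 observation axes into the leading component plane. Only this
orientation yields a per-protein Hotelling T², the squared Mahalanobis-type
distance of a protein from the multivariate centre computed in the retained
component subspace:

    T²_i = Σ_{k ≤ m} s_ik² / λ_k,

where s_ik is protein i's score on component k, λ_k the component's variance,
and m the smallest number of components reaching the variance target (default
90%). Proteins with T² above the third quartile of all T² values are flagged as
the extreme, most differentially expressed subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ContractError
from .io_tables import QuantTable

__all__ = [
    "ExpressionMatrix",
    "PcaResult",
    "build_matrix",
    "run_pca",
    "hotelling_rank",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Protein x observation grid of log2 ratios with a mask of imputed cells."""

    values: np.ndarray  # shape (n_proteins, n_observations), no NaN
    missing_mask: np.ndarray  # True where the cell was missing before imputation
    protein_ids: list[str]
    observation_keys: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ContractError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.protein_ids), len(self.observation_keys)):
            raise ContractError("matrix shape does not match id lists")
        if len(set(self.observation_keys)) != len(self.observation_keys):
            raise ContractError("observation keys must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, obs: str) -> np.ndarray:
        return self.values[:, self.observation_keys.index(obs)]

    def observed(self, obs: str) -> np.ndarray:
        """Non-imputed values of one observation column."""
        j = self.observation_keys.index(obs)
        return self.values[~self.missing_mask[:, j], j]


def build_matrix(
    table: QuantTable,
    observations: list[str] | None = None,
    impute: str = "zero",
    mask_nonsignificant_alpha: float | None = None,
) -> ExpressionMatrix:
    """Assemble the protein x observation log2-ratio matrix.

    Missing cells are handled per ``impute``: ``"zero"`` substitutes 0 — the
    no-change log2 ratio, mirroring the convention of assigning a no-significant-
    change expression value to missing points — while ``"drop"`` removes any
    protein row with a missing cell. Rows missing in every listed observation are
    always dropped (with a logged warning). When ``mask_nonsignificant_alpha`` is
    set, cells whose ratio-test p is at or above that level are additionally
    treated as missing before imputation.
    """
    observations = list(observations or table.observations)
    unknown = set(observations) - set(table.observations)
    if unknown:
        raise ContractError(f"observations not in table: {sorted(unknown)}")
    if impute not in ("zero", "drop"):
        raise ContractError(f"impute must be 'zero' or 'drop', got {impute!r}")

    rows, mask_rows, ids = [], [], []
    n_dropped_empty = 0
    for rec in table.proteins:
        values, mask = [], []
        for obs in observations:
            v, p = rec.log2_ratio(obs), rec.p_value(obs)
            missing = v is None
            if (
                not missing
                and mask_nonsignificant_alpha is not None
                and (p is None or p >= mask_nonsignificant_alpha)
            ):
                missing = True
            values.append(0.0 if missing else v)
            mask.append(missing)
        if all(mask):
            n_dropped_empty += 1
            continue
        if impute == "drop" and any(mask):
            continue
        rows.append(values)
        mask_rows.append(mask)
        ids.append(rec.accession)
    if n_dropped_empty:
        logger.warning("dropped %d all-missing protein rows", n_dropped_empty)
    return ExpressionMatrix(
        np.asarray(rows, dtype=float).reshape(len(ids), len(observations)),
        np.asarray(mask_rows, dtype=bool).reshape(len(ids), len(observations)),
        ids,
        observations,
    )


@dataclass
class PcaResult:
    """Scores, loadings and variance decomposition of a protein-space PCA."""

    scores: np.ndarray  # proteins x components
    loadings: np.ndarray  # observations x components, orthonormal columns
    explained_variance: np.ndarray  # λ_k, sample-covariance eigenvalues
    explained_fraction: np.ndarray  # λ_k / Σλ
    column_means: np.ndarray
    protein_ids: list[str]
    observation_keys: list[str]
    scaled: bool

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def components_for_variance(self, variance_target: float) -> int:
        """Smallest component count whose cumulative explained fraction reaches the target."""
        if not (0.0 < variance_target <= 1.0):
            raise ContractError("variance_target must lie in (0, 1]")
        cumulative = np.cumsum(self.explained_fraction)
        return int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)


def run_pca(matrix: ExpressionMatrix, center: bool = True, scale: bool = False) -> PcaResult:
    """Principal component analysis of the expression matrix.

    Columns are mean-centred by default and not variance-scaled (set ``scale``
    to standardise each observation first). All min(n-1, p) components are kept.
    """
    n, p = matrix.shape
    if n < 2 or p < 2:
        raise ContractError("PCA needs at least 2 proteins and 2 observations")
    values = matrix.values.astype(float)
    if scale:
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ContractError("cannot scale: zero-variance observation column")
        values = values / sd
    total_var = values.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        raise ContractError("matrix has zero total variance")

    if center:
        n_components = min(n - 1, p)
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(values)
        loadings = pca.components_.T
        lam = pca.explained_variance_
        means = pca.mean_
    else:
        # uncentred variant: axes of the raw second-moment matrix
        n_components = min(n, p)
        _, s, vt = np.linalg.svd(values, full_matrices=False)
        loadings = vt.T[:, :n_components]
        scores = values @ loadings
        lam = (s[:n_components] ** 2) / max(n - 1, 1)
        means = np.zeros(p)
    fraction = lam / lam.sum() if lam.sum() > 0 else lam
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance=lam,
        explained_fraction=fraction,
        column_means=means,
        protein_ids=list(matrix.protein_ids),
        observation_keys=list(matrix.observation_keys),
        scaled=scale,
    )


@dataclass
class HotellingRanking:
    """Per-protein T² values with the above-third-quartile extreme subset."""

    protein_ids: list[str]  # sorted by T² descending
    t2: np.ndarray  # aligned with protein_ids
    n_components_used: int
    q3: float
    selected: list[str]  # proteins with T² strictly greater than q3


def hotelling_rank(pca: PcaResult, variance_target: float = 0.90) -> HotellingRanking:
    """Rank proteins by Hotelling T² computed in the retained component subspace.

    ``variance_target`` picks m = the smallest component count explaining at
    least that fraction of variance. Components with zero variance among the
    retained ones are skipped with a warning. The selected subset contains the
    proteins with T² strictly above the third quartile (linear-interpolation
    quantile) of all T² values.
    """
    m = pca.components_for_variance(variance_target)
    lam = pca.explained_variance[:m]
    usable = lam > 0
    if not np.all(usable):
        warnings.warn(
            "skipping zero-variance components in Hotelling T²", RuntimeWarning
        )
    scores = pca.scores[:, :m][:, usable]
    lam = lam[usable]
    t2 = np.square(scores / np.sqrt(lam)).sum(axis=1)
    order = np.argsort(-t2, kind="stable")
    ranked_ids = [pca.protein_ids[i] for i in order]
    ranked_t2 = t2[order]
    q3 = float(np.quantile(t2, 0.75))  # linear interpolation, the numpy default
    selected = [pid for pid, value in zip(ranked_ids, ranked_t2) if value > q3]
    return HotellingRanking(ranked_ids, ranked_t2, int(usable.sum()), q3, selected)
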