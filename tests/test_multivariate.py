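"""PCA against eigendecomposition oracles and Hotelling T² against Mahalanobis."""

import numpy as np
import pytest

from conftest import make_matrix
from octofactor.errors import ContractError
from octofactor.multivariate import build_matrix, hotelling_rank, run_pca
from octofactor.io_tables import ObservationRatio, ProteinRecord, QuantTable


def random_matrix(n, p, seed=0):
    rng = np.random.default_rng(seed)
    return make_matrix(rng.normal(0, 1, size=(n, p)))


class TestBuildMatrix:
    def test_zero_imputation(self):
        proteins = [
            ProteinRecord(
                accession="P1",
                ratios={
                    "116:114": ObservationRatio("116", "114", 1.5, 0.01),
                    "121:114": ObservationRatio("121", "114", None, None),
                },
            )
        ]
        table = QuantTable(proteins, ["116:114", "121:114"])
        matrix = build_matrix(table)
        assert matrix.values.tolist() == [[1.5, 0.0]]
        assert matrix.missing_mask.tolist() == [[False, True]]

    def test_fully_observed_identity(self, interaction_table):
        matrix = build_matrix(interaction_table)
        assert matrix.shape == (45, 2)
        assert not matrix.missing_mask.any()
        assert matrix.column("116:114")[2] == pytest.approx(2.92)  # Gstm1

    def test_all_missing_row_dropped(self):
        proteins = [
            ProteinRecord(
                accession="P1",
                ratios={"116:114": ObservationRatio("116", "114", None, None)},
            ),
            ProteinRecord(
                accession="P2",
                ratios={"116:114": ObservationRatio("116", "114", 1.0, 0.01)},
            ),
        ]
        table = QuantTable(proteins, ["116:114"])
        matrix = build_matrix(table)
        assert matrix.protein_ids == ["P2"]

    def test_drop_policy(self):
        proteins = [
            ProteinRecord(
                accession="P1",
                ratios={
                    "116:114": ObservationRatio("116", "114", 1.0, 0.01),
                    "121:114": ObservationRatio("121", "114", None, None),
                },
            ),
            ProteinRecord(
                accession="P2",
                ratios={
                    "116:114": ObservationRatio("116", "114", 1.0, 0.01),
                    "121:114": ObservationRatio("121", "114", 2.0, 0.01),
                },
            ),
        ]
        table = QuantTable(proteins, ["116:114", "121:114"])
        assert build_matrix(table, impute="drop").protein_ids == ["P2"]


class TestPca:
    def test_explained_variance_matches_covariance_eigenvalues(self):
        matrix = random_matrix(20, 4, seed=1)
        result = run_pca(matrix)
        eigenvalues = np.sort(np.linalg.eigvalsh(np.cov(matrix.values.T)))[::-1]
        assert result.explained_variance == pytest.approx(eigenvalues[:4], rel=1e-9)
        assert result.explained_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(result.explained_fraction) <= 1e-12)

    def test_reconstruction(self):
        matrix = random_matrix(15, 5, seed=2)
        result = run_pca(matrix)
        reconstructed = result.scores @ result.loadings.T + result.column_means
        assert reconstructed == pytest.approx(matrix.values, abs=1e-9)

    def test_loadings_orthonormal(self):
        result = run_pca(random_matrix(30, 6, seed=3))
        gram = result.loadings.T @ result.loadings
        assert gram == pytest.approx(np.eye(result.n_components), abs=1e-9)

    def test_single_varying_column(self):
        values = np.zeros((10, 3))
        values[:, 1] = np.arange(10)
        result = run_pca(make_matrix(values))
        assert result.explained_fraction[0] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ContractError):
            run_pca(make_matrix(np.ones((5, 3))))

    def test_needs_two_observations(self):
        with pytest.raises(ContractError):
            run_pca(make_matrix(np.random.default_rng(0).normal(size=(5, 1))))


class TestHotelling:
    def test_full_rank_equals_mahalanobis(self):
        matrix = random_matrix(25, 5, seed=4)
        result = run_pca(matrix)
        ranking = hotelling_rank(result, variance_target=1.0)
        x = matrix.values
        mu = x.mean(axis=0)
        inv_cov = np.linalg.inv(np.cov(x.T))
        expected = {
            pid: float((row - mu) @ inv_cov @ (row - mu))
            for pid, row in zip(matrix.protein_ids, x)
        }
        got = dict(zip(ranking.protein_ids, ranking.t2))
        for pid in expected:
            assert got[pid] == pytest.approx(expected[pid], rel=1e-8)

    def test_mean_point_has_zero_t2(self):
        rng = np.random.default_rng(5)
        half = rng.normal(0, 1, size=(10, 3))
        values = np.vstack([half, -half, np.zeros(3)])  # last row = column mean
        matrix = make_matrix(values)
        ranking = hotelling_rank(run_pca(matrix), variance_target=1.0)
        centre = dict(zip(ranking.protein_ids, ranking.t2))[matrix.protein_ids[-1]]
        assert centre == pytest.approx(0.0, abs=1e-12)

    def test_third_quartile_subset_size(self):
        # tie-free distances: selected count is n - ceil(0.75(n-1)+1) + ... ~= n/4
        matrix = random_matrix(40, 4, seed=6)
        ranking = hotelling_rank(run_pca(matrix), variance_target=1.0)
        assert len(ranking.selected) == 10  # strictly above Q3 of 40 tie-free values
        assert all(t >= 0 for t in ranking.t2)

    def test_component_count_from_variance_target(self):
        values = np.zeros((30, 3))
        rng = np.random.default_rng(7)
        values[:, 0] = rng.normal(0, 10, 30)
        values[:, 1] = rng.normal(0, 1, 30)
        values[:, 2] = rng.normal(0, 0.1, 30)
        result = run_pca(make_matrix(values))
        assert result.components_for_variance(0.5) == 1
        assert result.components_for_variance(1.0) == 3
        with pytest.raises(ContractError):
            result.components_for_variance(0.0)
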