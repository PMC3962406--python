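"""End-to-end orchestration: filter → pca → anova → hclust → kmeans → regulators.

Each stage writes a plain TSV (prefixed with a one-line ``#`` provenance
header) into the output directory, and the run finishes with a JSON manifest
recording package version, configuration, input checksums and per-stage
status. Stage outputs are pure functions of (inputs, config, seed), so two
runs with the same config produce identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import OctofactorError, ValidationError
from .io_tables import read_network, read_quant_table
from .significance import SignificanceCriteria, significant_proteins, changed_proteins

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    quant_table: Path
    out_dir: Path
    network: Path | None = None
    observations: list[str] | None = None  # default: all observations in the table
    filter_obs: str | None = None  # observation for the significance filter stage
    kmeans_obs: tuple[str, str] = ("116:114", "121:114")
    min_abs_log2: float = 1.0
    alpha: float = 0.05
    variance_target: float = 0.90
    family_alpha: float = 0.05
    k: int = 3
    seed: int = 0
    restarts: int = 10
    background_size: int | None = None
    regulator_obs: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in ("quant_table", "out_dir", "network"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "kmeans_obs" in kwargs:
            kwargs["kmeans_obs"] = tuple(kwargs["kmeans_obs"])
        return cls(**kwargs)

    def validate(self) -> None:
        problems = []
        if not Path(self.quant_table).exists():
            problems.append(f"quant table not found: {self.quant_table}")
        if self.network is not None and not Path(self.network).exists():
            problems.append(f"network not found: {self.network}")
        if problems:
            raise ValidationError("; ".join(problems))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages and return the run manifest (also written to disk).

    Stages after a failed stage are skipped; the manifest marks the failure and
    the partial outputs are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = f"octofactor {__version__} seed={config.seed}"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_abs_log2": config.min_abs_log2,
            "alpha": config.alpha,
            "variance_target": config.variance_target,
            "family_alpha": config.family_alpha,
            "k": config.k,
        },
        "inputs": {"quant_table": _sha256(Path(config.quant_table))},
        "stages": {},
    }
    if config.network is not None:
        manifest["inputs"]["network"] = _sha256(Path(config.network))

    table = read_quant_table(config.quant_table)
    observations = config.observations or table.observations
    failed = False

    def _stage(name: str, fn) -> None:
        nonlocal failed
        if failed:
            manifest["stages"][name] = {"status": "skipped"}
            return
        start = time.perf_counter()
        try:
            outputs = fn()
        except OctofactorError as exc:
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True
            return
        elapsed = time.perf_counter() - start
        logger.info("stage %s done in %.2fs", name, elapsed)
        manifest["stages"][name] = {
            "status": "complete",
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def stage_filter() -> list[Path]:
        obs = config.filter_obs or observations[0]
        result = significant_proteins(
            table, obs, SignificanceCriteria(config.min_abs_log2, config.alpha)
        )
        df = result.table.to_frame()
        df.insert(0, "accession", df.index)
        path = out_dir / "filter.tsv"
        _write_tsv(
            df.reset_index(drop=True),
            path,
            f"{provenance} stage=filter obs={obs} n={result.n} up={result.n_up} down={result.n_down}",
        )
        return [path]

    def stage_pca() -> list[Path]:
        from .multivariate import build_matrix, hotelling_rank, run_pca

        changed = changed_proteins(table, observations, config.alpha)
        matrix = build_matrix(changed, observations)
        pca = run_pca(matrix)
        ranking = hotelling_rank(pca, config.variance_target)
        scores = pd.DataFrame(
            pca.scores,
            index=pca.protein_ids,
            columns=[f"PC{i+1}" for i in range(pca.n_components)],
        )
        scores.insert(0, "accession", scores.index)
        t2 = pd.DataFrame(
            {
                "accession": ranking.protein_ids,
                "t2": ranking.t2,
                "selected": [pid in set(ranking.selected) for pid in ranking.protein_ids],
            }
        )
        variance = pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(pca.n_components)],
                "variance": pca.explained_variance,
                "fraction": pca.explained_fraction,
            }
        )
        paths = []
        for name, df in (("pca_scores", scores.reset_index(drop=True)),
                         ("pca_t2", t2), ("pca_variance", variance)):
            path = out_dir / f"{name}.tsv"
            _write_tsv(df, path, f"{provenance} stage=pca")
            paths.append(path)
        return paths

    def stage_anova() -> list[Path]:
        from .group_compare import observation_anova, tukey_kramer
        from .multivariate import build_matrix

        changed = changed_proteins(table, observations, config.alpha)
        matrix = build_matrix(changed, observations)
        anova = observation_anova(matrix)
        pairs = tukey_kramer(matrix, config.family_alpha)
        df = pd.DataFrame(
            {
                "obs_a": [c.obs_pair[0] for c in pairs],
                "obs_b": [c.obs_pair[1] for c in pairs],
                "mean_difference": [c.mean_difference for c in pairs],
                "ci_low": [c.ci_low for c in pairs],
                "ci_high": [c.ci_high for c in pairs],
                "significant": [c.significant for c in pairs],
            }
        )
        path = out_dir / "anova_pairs.tsv"
        _write_tsv(
            df,
            path,
            f"{provenance} stage=anova F={anova.f_statistic:.4g} p={anova.p_value:.4g}",
        )
        return [path]

    def stage_hclust() -> list[Path]:
        from .hier_cluster import cluster_observations, normalize_within_observation
        from .multivariate import build_matrix

        changed = changed_proteins(table, observations, config.alpha)
        matrix = build_matrix(changed, observations)
        dendrogram = cluster_observations(normalize_within_observation(matrix))
        merges = pd.DataFrame(
            dendrogram.linkage_matrix, columns=["left", "right", "height", "size"]
        )
        labels = pd.DataFrame(
            {
                "observation": dendrogram.observation_keys,
                "two_way_label": [
                    dendrogram.two_way_labels[k] for k in dendrogram.observation_keys
                ],
            }
        )
        paths = []
        for name, df in (("hclust_merges", merges), ("hclust_labels", labels)):
            path = out_dir / f"{name}.tsv"
            _write_tsv(df, path, f"{provenance} stage=hclust")
            paths.append(path)
        return paths

    def stage_kmeans() -> list[Path]:
        from .interaction_kmeans import deviation_points, kmean_deviation

        obs_a, obs_b = config.kmeans_obs
        pair = changed_proteins(table, [obs_a, obs_b], config.alpha)
        points = deviation_points(pair, obs_a, obs_b)
        km = kmean_deviation(points, k=config.k, restarts=config.restarts, seed=config.seed)
        symbols = table.gene_symbols()
        df = pd.DataFrame(
            {
                "accession": [p.protein_id for p in km.points],
                "gene_symbol": [symbols.get(p.protein_id, "") for p in km.points],
                "e_a": [p.e_a for p in km.points],
                "e_b": [p.e_b for p in km.points],
                "distance": [p.distance for p in km.points],
                "section": [p.section for p in km.points],
                "cluster": [p.cluster for p in km.points],
            }
        )
        path = out_dir / "kmeans.tsv"
        _write_tsv(df, path, f"{provenance} stage=kmeans obs_a={obs_a} obs_b={obs_b}")
        return [path]

    def stage_regulators() -> list[Path]:
        from .regulator_activation import score_regulators_from_table

        network = read_network(config.network)
        obs = config.regulator_obs or config.kmeans_obs[0]
        dataset = changed_proteins(table, [obs], config.alpha)
        background = config.background_size or len(table)
        scores = score_regulators_from_table(dataset, obs, network, background)
        df = pd.DataFrame(
            {
                "regulator": [s.regulator for s in scores],
                "n_targets": [s.n_targets_in_dataset for s in scores],
                "n_consistent": [s.n_consistent for s in scores],
                "n_inconsistent": [s.n_inconsistent for s in scores],
                "z": [s.z for s in scores],
                "overlap_p": [s.overlap_p for s in scores],
                "predicted_state": [s.predicted_state for s in scores],
            }
        )
        path = out_dir / "regulators.tsv"
        _write_tsv(df, path, f"{provenance} stage=regulators obs={obs}")
        return [path]

    _stage("filter", stage_filter)
    _stage("pca", stage_pca)
    _stage("anova", stage_anova)
    _stage("hclust", stage_hclust)
    _stage("kmeans", stage_kmeans)
    if config.network is not None:
        _stage("regulators", stage_regulators)

    manifest["failed"] = failed
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
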