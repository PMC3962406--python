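"""Synthetic 8-channel factorial proteome tables with known ground truth.

The generator emulates the study design: eight reporter channels covering the
knockout x ethanol x gender factorial, with the dextrose-fed wild-type male
channel as reference, so each protein yields seven log2 ratios. For each
protein and condition the *true* log2 ratio is

    beta_ko*KO + beta_e*E + beta_g*G + beta_ko_x_e*KO*E,

where each main-effect or interaction coefficient applies only to the proteins
drawn as carriers of that effect (disjoint carrier sets by default). Observed
replicate-level log2 ratios add Gaussian noise; the per-observation summary is
the replicate mean, and the ratio p-value is a two-sided one-sample t test of
the replicates against zero — a transparent stand-in for a quantification
engine's ratio statistics. Cells go missing independently with a fixed
probability.

Default parameters mirror the study's scale: 863 quantified proteins, four
peptide-level replicates per channel (the study ran four mice per condition),
a dominant knockout main effect over ethanol over gender, and a negative
knockout x ethanol interaction (the knockout reverses part of the ethanol
response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import CHANNEL_CONDITIONS, DEFAULT_OBSERVATIONS
from .errors import ValidationError
from .io_tables import ObservationRatio, ProteinRecord, QuantTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "null_config",
    "interaction_only_config",
    "location_test_power",
    "RecoveryReport",
    "recovery_suite",
]

EFFECTS = ("ko", "e", "g", "ko_x_e")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the factorial generator (log2-ratio units throughout)."""

    n_proteins: int = 863
    n_replicates: int = 4
    beta_ko: float = 2.0
    beta_e: float = 1.0
    beta_g: float = 0.4
    beta_ko_x_e: float = -1.5
    effect_fraction: float = 0.1
    noise_sd: float = 0.5
    missing_prob: float = 0.05
    overlapping_effects: bool = False
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_proteins < 1:
            problems.append("n_proteins must be >= 1")
        if self.n_replicates < 2:
            problems.append("n_replicates must be >= 2")
        if not (0.0 <= self.effect_fraction <= 1.0):
            problems.append("effect_fraction must lie in [0, 1]")
        if not (0.0 <= self.missing_prob <= 1.0):
            problems.append("missing_prob must lie in [0, 1]")
        if not self.noise_sd > 0:
            problems.append("noise_sd must be > 0")
        if not self.overlapping_effects and 3 * self.effect_fraction > 1.0:
            problems.append(
                "disjoint carrier sets need effect_fraction <= 1/3"
            )
        if problems:
            raise ValidationError("; ".join(problems))


def null_config(**overrides) -> SyntheticConfig:
    """All effects zero: the global null, used for error-rate calibration."""
    base = dict(beta_ko=0.0, beta_e=0.0, beta_g=0.0, beta_ko_x_e=0.0)
    base.update(overrides)
    return SyntheticConfig(**base)


def interaction_only_config(**overrides) -> SyntheticConfig:
    """Only the knockout x ethanol interaction is active.

    Under this configuration the deviation-distance K-means is the only stage
    with signal, so its farthest cluster should consist of interaction carriers.
    """
    base = dict(beta_ko=0.0, beta_e=0.0, beta_g=0.0, beta_ko_x_e=-1.5)
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class GroundTruth:
    """Which effects each protein carries, and its true log2 ratio per observation."""

    effects: pd.DataFrame  # protein x EFFECTS boolean carrier flags
    true_log2: pd.DataFrame  # protein x observation true values

    def total_magnitude(self) -> pd.Series:
        """Euclidean norm of the true log2 ratio vector, per protein."""
        return np.sqrt((self.true_log2 ** 2).sum(axis=1))


def _carrier_flags(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign effect-carrier proteins.

    Default layout: the knockout, ethanol and interaction programmes are
    disjoint protein sets, while the gender effect is carried by the
    ethanol-responsive proteins — gender differences in this design manifest
    as a modulation of the ethanol response, which is what couples the
    gender-only condition to the ethanol conditions rather than to the
    knockout ones. With ``overlapping_effects`` every carrier set is drawn
    independently instead.
    """
    n = config.n_proteins
    n_each = int(round(config.effect_fraction * n))
    flags = pd.DataFrame(
        False, index=[f"SYN{i:05d}" for i in range(n)], columns=list(EFFECTS)
    )
    if config.overlapping_effects:
        for eff in EFFECTS:
            chosen = rng.choice(n, size=n_each, replace=False)
            flags.iloc[chosen, flags.columns.get_loc(eff)] = True
    else:
        order = rng.permutation(n)
        for idx, eff in enumerate(("ko", "e", "ko_x_e")):
            chosen = order[idx * n_each : (idx + 1) * n_each]
            flags.iloc[chosen, flags.columns.get_loc(eff)] = True
        # gender rides on the ethanol-responsive programme
        chosen = order[n_each : 2 * n_each]
        flags.iloc[chosen, flags.columns.get_loc("g")] = True
    return flags


def generate(config: SyntheticConfig) -> tuple[QuantTable, GroundTruth]:
    """Draw one synthetic quant table and its ground truth.

    Deterministic given the config (a single RNG stream is seeded from
    ``config.seed``): the same config yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    observations = list(DEFAULT_OBSERVATIONS)
    flags = _carrier_flags(config, rng)
    betas = {
        "ko": config.beta_ko,
        "e": config.beta_e,
        "g": config.beta_g,
        "ko_x_e": config.beta_ko_x_e,
    }

    # true log2 ratio of each observation for each protein
    truth = np.zeros((config.n_proteins, len(observations)))
    for j, obs in enumerate(observations):
        tag = obs.split(":")[0]
        cond = CHANNEL_CONDITIONS[tag]
        design = {
            "ko": cond.knockout,
            "e": cond.ethanol,
            "g": cond.female,
            "ko_x_e": cond.knockout and cond.ethanol,
        }
        for eff in EFFECTS:
            if design[eff]:
                truth[:, j] += betas[eff] * flags[eff].to_numpy()

    reps = truth[:, :, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_proteins, len(observations), config.n_replicates)
    )
    observed = reps.mean(axis=2)
    t_res = stats.ttest_1samp(reps, popmean=0.0, axis=2)
    p_values = np.asarray(t_res.pvalue)
    missing = rng.random((config.n_proteins, len(observations))) < config.missing_prob

    proteins = []
    for i, accession in enumerate(flags.index):
        ratios = {}
        for j, obs in enumerate(observations):
            num, den = obs.split(":")
            if missing[i, j]:
                ratios[obs] = ObservationRatio(num, den, None, None)
            else:
                p = float(min(max(p_values[i, j], 0.0), 1.0))
                ratios[obs] = ObservationRatio(num, den, float(observed[i, j]), p)
        proteins.append(
            ProteinRecord(
                accession=accession,
                gene_symbol=f"Gene{i:05d}",
                function_tag="synthetic",
                protein_name=f"Synthetic protein {i}",
                ratios=ratios,
            )
        )
    table = QuantTable(proteins, observations)
    ground_truth = GroundTruth(
        effects=flags,
        true_log2=pd.DataFrame(truth, index=flags.index, columns=observations),
    )
    return table, ground_truth


def location_test_power(
    effect: float, noise_sd: float, n_replicates: int, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided one-sample t test at the generator's settings.

    Noncentral-t computation: the test rejects when |T| exceeds the central-t
    critical value; under an effect, T follows a noncentral t with
    delta = effect / (noise_sd / sqrt(n)).
    """
    df = n_replicates - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    delta = effect / (noise_sd / math.sqrt(n_replicates))
    return float(
        1 - stats.nct.cdf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta)
    )


@dataclass
class RecoveryReport:
    """Pipeline-recovery summary over repeated simulations."""

    n_simulations: int
    ko_separation_rate: float  # fraction of runs whose two-way cut isolates the KO conditions
    tukey_any_significant_rate: float  # fraction of runs with >= 1 significant pair
    interaction_odds_ratio: float  # enrichment of interaction carriers in the farthest cluster
    interaction_counts: tuple[int, int, int, int]  # (carrier&far, carrier&near, other&far, other&near)
    t2_truth_spearman: float  # rank agreement of T2 with true effect magnitude (nan if truth flat)


def recovery_suite(
    config: SyntheticConfig | None = None,
    n_simulations: int = 200,
    seed: int = 0,
    family_alpha: float = 0.05,
    checks: tuple[str, ...] = ("hclust", "tukey", "kmeans", "t2"),
) -> RecoveryReport:
    """Run the full pipeline on repeated synthetic draws and summarise recovery.

    Per draw: generate a table, keep proteins changed (p < 0.05) in >= 1
    observation, then (i) test whether the hierarchical two-way cut separates
    knockout from wild-type conditions, (ii) run Tukey-Kramer across the seven
    observations, (iii) cluster the ethanol vs knockout+ethanol deviation
    distances with K-means (k=3) and tally interaction carriers in the farthest
    cluster, and (iv) correlate Hotelling T² with the true effect magnitude.
    ``checks`` selects which of the four to run (skipped rates report nan /
    zero counts), which keeps calibration runs that only need one stage cheap.
    """
    from .group_compare import tukey_kramer
    from .hier_cluster import cluster_observations, normalize_within_observation
    from .interaction_kmeans import deviation_points, kmean_deviation
    from .multivariate import build_matrix, hotelling_rank, run_pca
    from .significance import changed_proteins

    config = config or SyntheticConfig()
    ko_obs = {
        obs
        for obs in DEFAULT_OBSERVATIONS
        if CHANNEL_CONDITIONS[obs.split(":")[0]].knockout
    }
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_simulations)

    n_separated = 0
    n_tukey_hit = 0
    carrier_far = carrier_near = other_far = other_near = 0
    spearmans: list[float] = []

    for sub_seed in sub_seeds:
        table, truth = generate(replace(config, seed=int(sub_seed)))
        changed = changed_proteins(table, table.observations, alpha=0.05)
        if len(changed) < 3:
            continue
        matrix = None
        if {"hclust", "tukey", "t2"} & set(checks):
            matrix = build_matrix(changed, table.observations, impute="zero")

        if "hclust" in checks:
            dendrogram = cluster_observations(normalize_within_observation(matrix))
            part_a, part_b = dendrogram.partition()
            if part_a == ko_obs or part_b == ko_obs:
                n_separated += 1

        if "tukey" in checks and any(
            c.significant for c in tukey_kramer(matrix, family_alpha)
        ):
            n_tukey_hit += 1

        if "t2" in checks:
            pca = run_pca(matrix)
            ranking = hotelling_rank(pca)
            t2 = pd.Series(ranking.t2, index=ranking.protein_ids)
            magnitude = truth.total_magnitude().loc[t2.index]
            if magnitude.nunique() > 1:
                rho = stats.spearmanr(t2.to_numpy(), magnitude.to_numpy()).statistic
                spearmans.append(float(rho))

        if "kmeans" in checks:
            pair = changed_proteins(table, ["116:114", "121:114"], alpha=0.05)
            points = deviation_points(pair, "116:114", "121:114")
            if len({round(p.distance, 12) for p in points}) >= 3:
                km = kmean_deviation(points, k=3, seed=int(sub_seed))
                far = max(p.cluster for p in km.points)
                carriers = set(truth.effects.index[truth.effects["ko_x_e"]])
                for p in km.points:
                    is_far = p.cluster == far
                    if p.protein_id in carriers:
                        carrier_far += is_far
                        carrier_near += not is_far
                    else:
                        other_far += is_far
                        other_near += not is_far

    # Haldane-corrected odds ratio to tolerate empty cells
    odds = ((carrier_far + 0.5) * (other_near + 0.5)) / (
        (carrier_near + 0.5) * (other_far + 0.5)
    )
    nan = float("nan")
    return RecoveryReport(
        n_simulations=n_simulations,
        ko_separation_rate=n_separated / n_simulations if "hclust" in checks else nan,
        tukey_any_significant_rate=n_tukey_hit / n_simulations if "tukey" in checks else nan,
        interaction_odds_ratio=float(odds) if "kmeans" in checks else nan,
        interaction_counts=(carrier_far, carrier_near, other_far, other_near),
        t2_truth_spearman=float(np.mean(spearmans)) if spearmans else nan,
    )
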