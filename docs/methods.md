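# Methods

## Data model

A quantification table holds, per protein, a log2 expression ratio and a
ratio-test p-value for each *observation* — a (numerator, denominator)
reporter-channel pair written `num:den`, e.g. `116:114`. All analyses operate
on `log2 R`, so 0 means "no change". The default channel-to-condition map is
the 2×2×2 factorial used throughout: tags 113–121 cover
{wild-type, CYP2E1-knockout} × {dextrose, ethanol} × {male, female}, with
114 (wild-type / dextrose / male) the common reference; the seven informative
observations are the other channels over 114. A YAML map can replace this
layout for other designs.

Missing cells (written `-`) mean the quantification engine produced no ratio
for that channel pair. Printed summary tables often omit p-values because
their rows already passed a significance filter; the filter therefore applies
its p criterion only where a p is recorded (`require_p=True` restores strict
rejection). Missing ratios never pass any filter and never join overlap
counts.

## Significance criteria

A protein is *significantly changed* in an observation when `|log2 R| > 1`
(two-fold) **and** `p < 0.05`, both strict, so boundary values (exactly 1.0,
exactly 0.05) are excluded. No multiple-testing correction is applied across
proteins — a deliberate fidelity choice, stated rather than silently
"improved"; the criteria object makes both thresholds explicit for callers
who want otherwise. The broader *expression changed* filter (input to PCA,
ANOVA, clustering) keeps proteins with `p < 0.05` in at least one listed
observation, with no fold-change requirement.

Up/down classification uses the sign of `log2 R`; a passing protein cannot
have `log2 R = 0` because the fold threshold is positive.

## PCA and Hotelling T²

Proteins are the PCA samples and observations the variables — the only
orientation that yields a per-protein outlyingness score and matches a biplot
that projects the seven observations as variable vectors. Columns are
mean-centred but not variance-scaled by default (scaling is a flag): the
ratios share units (log2) and scaling would equalise the very factor
magnitudes the analysis compares. Missing cells are imputed with 0, the
no-change value, before matrix analyses (policy `zero`; `drop` removes
incomplete rows instead).

Hotelling's statistic for protein *i* uses the scores `s_ik` and component
variances `λ_k` of the leading m components,

    T²_i = Σ_{k≤m} s_ik² / λ_k ,

with m the smallest count whose cumulative explained-variance fraction
reaches the target (default 0.90). This variance-target rule generalises the
"top six components" convention beyond seven observations. With every
component retained T² equals the squared Mahalanobis distance to the column
mean — the oracle used in tests. Zero-variance components among the retained
ones are skipped with a warning. The *extreme* subset contains proteins with
T² strictly greater than the third quartile of all T² values; the quartile
uses the linear-interpolation definition (numpy default). Ties at the
quartile are excluded by the strict inequality.

## ANOVA and Tukey–Kramer

The one-way fixed-effects ANOVA treats each observation column as a group of
protein-level log2 ratios and proteins as independent replicates within a
group. This mirrors how the changed-protein set is used as the ANOVA sample
in the motivating analysis; it deliberately ignores protein-level pairing
across columns, which is documented here as a fidelity choice, not an
oversight. Imputed cells are excluded (group sizes may differ);
`include_imputed=True` reproduces the imputed variant.

Pairwise comparison uses the Tukey–Kramer construction: for groups i, j the
interval is `(x̄_i − x̄_j) ± q_{α,k,df}/√2 · √(MS_within (1/n_i + 1/n_j))`,
with the studentized-range quantile computed numerically (cross-checked
against R's `qtukey` and scipy's independent implementation in the tests); a
pair is significant iff its interval excludes 0. With equal group sizes this
reduces exactly to Tukey's HSD.

Calibration: on null simulations the family-wise error tracks the nominal
level. The changed-protein selection step makes the realised rate mildly
conservative (measured a few points below 5 % in some seed batches) because
selection inflates within-group spread relative to the between-mean spread;
the recovery suite reports the measured rate rather than assuming the
nominal one.

## Hierarchical clustering of observations

Observation columns are standardised within observation (mean 0, sd 1,
sample n−1 convention; population convention available) and clustered
agglomeratively with Euclidean distance and complete linkage. Imputation
happens *before* normalisation so the imputed value keeps its "no change"
meaning. The two-way cut at the top split is the reported partition; with a
dominant knockout effect it separates knockout from wild-type conditions.
Protein-side clustering (`cluster_proteins`) is available for the heatmap's
row dendrogram but is not part of the validated surface.

## Interaction K-means

For the ethanol (`E_a`, x-axis) versus knockout+ethanol (`E_b`, y-axis)
comparison, a protein unaffected by the knockout lies on the identity line
`E_a = E_b`. The *equal-expression deviation* is the perpendicular distance

    D = |E_a − E_b| / √2 .

"Deviation from equal expression" fixes this distance only up to a positive
scale factor; the perpendicular form is adopted, and because 1-D K-means
partitions are invariant to positive rescaling, the choice cannot change any
cluster membership (a property test asserts this). Clustering is on the
scalar D, not the 2-D point: clusters are then bands around the identity
line, and a point and its mirror image always share a cluster — consistent
with the farthest band containing members on both sides of the line.

K-means (k = 3 by default) is solved *exactly*: the optimal 1-D partition is
contiguous in sorted order, so a dynamic programme over prefix cut points
(O(k n²), vectorised) returns the global minimiser of the within-cluster sum
of squares. Lloyd-style iteration with random restarts was considered and
rejected because it can converge to a second stable fixed point on small
instances; the exact solver is deterministic, needs no seed, and matches the
brute-force enumeration of all contiguous partitions (the test oracle) by
construction. Labels are numbered by ascending centroid, so cluster 1 hugs
the line and cluster k is farthest. Sections: `lower_right` (`E_a > E_b`, knockout
blunts/reverses the ethanol response), `upper_left` (`E_a < E_b`, knockout
amplifies it), `on_line` (D = 0 exactly).

## Upstream-regulator activation

Given a signed regulator→target edge list (+1 = activation of the regulator
raises the target, −1 = lowers it) and the observed direction of each
dataset gene (sign of its log2 ratio), a target is *consistent with
activation* when direction equals edge sign. The activation z-score is

    z = (n_consistent − n_inconsistent) / √N ,  N = n_consistent + n_inconsistent,

with |z| ≥ 2 calling the regulator activated/inhibited. This is the
transparent, unweighted form of the score; commercial implementations add
proprietary edge weights and literature-bias corrections, so their printed
scores are approximated, not reproduced, by this package. Edges of unknown
sign and targets without an observed direction are excluded from N but still
count toward the overlap. The overlap p-value is the hypergeometric upper
tail of drawing at least the observed number of targets when sampling the
dataset from the quantified background (default background: all quantified
proteins, 863 in the packaged configuration; flag-overridable).

The packaged network records edge signs only where the source analysis
states them: the seven NRF2 targets (six up-regulated, FABP1 down-regulated)
and the eleven PPARα targets whose changes were reported as consistent with
PPARα inhibition (their signs are the negation of the observed 116:114
directions). All other edges are unsigned and enter only overlap counting.

## Synthetic-data generator

Each protein's true log2 ratio in a condition is
`β_ko·KO + β_e·E + β_g·G + β_kox e·KO·E`, each coefficient applying only to
its carrier proteins. Defaults (log2 units): 863 proteins (the quantified
set size), 4 replicates per channel (four mice per condition), β_ko = 2.0,
β_e = 1.0, β_g = 0.4, β_ko×e = −1.5 (the knockout reverses part of the
ethanol response), carrier fraction 0.1 per effect, replicate noise sd 0.5,
5 % missing cells. Observed per-observation values are replicate means; the
ratio p-value is a two-sided one-sample t test of the replicates against 0 —
a transparent stand-in for a quantification engine's proprietary ratio
statistics. A single RNG stream seeded from the config makes generation
byte-reproducible.

Carrier layout: knockout, ethanol and interaction carriers are disjoint
protein programmes; the gender effect rides on the ethanol-responsive
programme. This encodes the design's biology — sex differences in this
system manifest chiefly as modulation of the alcohol response — and it is
also what gives the condition dendrogram its observed structure: a
gender-only column uncorrelated with *both* sides of the tree (as fully
disjoint carriers would imply) makes the top split noise-driven, whereas
gender-on-ethanol carriers couple the female-control column to the ethanol
conditions. `overlapping_effects=True` draws all four carrier sets
independently instead.

What the generator does **not** emulate: reporter-ion ratio compression,
isotope impurity, peptide-to-protein rollup, shared-reference correlation
between observations, and non-Gaussian heavy tails of real log ratios.
Passing recovery tests therefore demonstrate internal consistency of the
pipeline under the stated model, not performance guarantees on real spectra.

The recovery suite reruns the pipeline on repeated draws and reports:
knockout/wild-type separation of the two-way cut (expected ≥ 95 % of runs
under the dominant-knockout default), the Tukey–Kramer family error under
the global null (expected ≈ the nominal 5 %), enrichment of interaction
carriers in the farthest K-means cluster under an interaction-only
configuration (odds ratio ≫ 1, Haldane-corrected), and the Spearman
correlation between T² and true effect magnitude. Simulation sizes (200
runs per check) keep each check to roughly a minute on one CPU.

## Numerical conventions and degenerate inputs

- Strict inequalities at every published threshold (fold change, alpha,
  third quartile, |z| ≥ 2 as printed).
- Quantiles: linear interpolation throughout.
- Standard deviations: sample (n−1) unless stated; the normalisation ddof is
  switchable.
- All-constant ANOVA input returns F = 0, p = 1 (the null is exactly true);
  a group with fewer than two values is a contract error naming the group.
- All-missing protein rows are dropped with a logged warning; zero-spread
  columns make normalisation a contract error.
- Re-referencing two observations (`log2(a/b) = log2(a/d) − log2(b/d)`)
  yields no derived p-value — it is not computable from ratio-level
  summaries.

## Known limitations

- Protein-level pairing across observations is ignored by the ANOVA stage
  (see above); a mixed-model treatment is out of scope.
- The regulator scorer needs a user-supplied network; it ships only the
  small transcribed fixture and performs no literature mining.
- The full-dataset reproduction test requires a transcription of the
  deposited supplementary quantification table, which is distributed as a
  binary spreadsheet and not packaged; without it that single test reports
  failure with instructions.
- T² ranking assumes the retained components capture real structure; with
  fewer proteins than observations the covariance is singular and the
  variance-target rule should be used with care.
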