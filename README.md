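# octofactor

Multifactorial analysis of 8-plex isobaric-label (iTRAQ) proteome ratio
tables, built for factorial designs of the form **knockout × treatment ×
sex**. The motivating application is a mouse-liver study of chronic alcohol
feeding: eight reporter channels (tags 113–121) label wild-type and CYP2E1
knockout mice of both sexes on ethanol or control diet, the dextrose-fed
wild-type male channel (114) serves as common reference, and each protein is
summarised by seven log2 ratios `log2 R` with a ratio-test p-value per
observation (an *observation* is a channel pair such as `116:114` = ethanol
vs control in wild-type males).

The package provides, as composable library functions:

- **Significance filtering & set comparison** — a protein is significantly
  changed when `|log2 R| > 1` and `p < 0.05` (strict inequalities); shared /
  unique / opposite-direction partitions between two observations.
- **PCA + Hotelling T²** — proteins are the samples, observations the
  variables; per-protein `T² = Σ_{k≤m} s_k²/λ_k` over the components
  explaining ≥ 90 % of variance flags the most extreme proteins (those above
  the third quartile of T²).
- **ANOVA + Tukey–Kramer** — one-way F test of equal mean expression change
  across observations, and studentized-range simultaneous pairwise intervals
  (valid for unequal group sizes).
- **Hierarchical clustering** — complete-linkage Euclidean clustering of
  observation columns after within-observation standardisation; the two-way
  cut exposes the dominant experimental factor.
- **Interaction K-means** — 1-D K-means (k = 3) on the
  *equal-expression deviation* `D = |E_a − E_b|/√2`, the perpendicular
  distance of a protein's (ethanol, knockout+ethanol) log2-ratio pair from
  the identity line; distant clusters collect proteins whose ethanol response
  the knockout reverses or amplifies.
- **Upstream-regulator scoring** — an open activation z-score
  `z = (consistent − inconsistent)/√N` over a user-supplied signed
  regulator→target edge list, plus a hypergeometric overlap p-value against
  the quantified background (|z| ≥ 2 calls activated/inhibited).
- **Synthetic data** — a factorial generator with per-protein effect carriers,
  replicate-level noise, ratio p-values and missingness, plus a recovery
  suite that reruns the whole pipeline on simulated data with known truth.

Packaged fixtures transcribe the study's printed tables: the 90-protein
male/female ethanol-response table, the 45-protein interaction-cluster table,
and the 8-regulator target network with observed target directions.

## Worked example

```python
from octofactor import SignificanceCriteria, datasets, overlap_analysis, significant_proteins

table = datasets.load_gender_table()          # 90 proteins, obs 116:114 & 115:113
male = significant_proteins(table, "116:114", SignificanceCriteria())
female = significant_proteins(table, "115:113", SignificanceCriteria())
print(male.n, male.n_up, male.n_down)          # 35 29 6
print(female.n, female.n_up, female.n_down)    # 67 32 35
report = overlap_analysis(male.table, female.table, "116:114", "115:113")
print(len(report.shared), len(report.only_a), len(report.only_b))  # 12 23 55
```

The numbers read: 35 proteins respond to ethanol in males (29 induced, 6
repressed) and 67 in females; 12 respond in both sexes, and exactly one of
those (`report.opposite_direction` → the folate enzyme FTCD) moves in
opposite directions — up in males, down in females.

More narrative walk-throughs live in `examples/` (one script per capability:
gender overlap, PCA/T², ANOVA/Tukey, interaction K-means, regulator scores,
synthetic recovery). A thin CLI wraps the same functions:

```bash
octofactor filter src/octofactor/data/ethanol_gender_table.tsv --obs 116:114
octofactor kmeans src/octofactor/data/interaction_cluster_table.tsv --seed 0
octofactor run --config run.yaml     # full pipeline with manifest
```

## Method notes

Model assumptions, parameter defaults, numerical conventions and known
limitations are documented in [`docs/methods.md`](docs/methods.md).
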