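"""ANOVA across the seven observations and Tukey-Kramer pairwise comparison.

On the default synthetic design the knockout+ethanol condition combines a
knockout main effect with a negative knockout x ethanol interaction, so pairs
contrasting knockout against wild-type conditions separate.
"""

from octofactor import (
    OBSERVATION_LABELS,
    SyntheticConfig,
    build_matrix,
    changed_proteins,
    generate,
    observation_anova,
    tukey_kramer,
)

table, _ = generate(SyntheticConfig(seed=7))
changed = changed_proteins(table, table.observations, alpha=0.05)
matrix = build_matrix(changed)

anova = observation_anova(matrix)
print(f"F = {anova.f_statistic:.2f}, p = {anova.p_value:.2g} "
      f"(df = {anova.df_between}, {anova.df_within})")

print("significant pairs at family alpha 0.05:")
for comp in tukey_kramer(matrix, family_alpha=0.05):
    if comp.significant:
        a, b = (OBSERVATION_LABELS.get(k, k) for k in comp.obs_pair)
        print(f"  {a:8s} vs {b:8s} mean diff {comp.mean_difference:+.3f} "
              f"[{comp.ci_low:+.3f}, {comp.ci_high:+.3f}]")
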