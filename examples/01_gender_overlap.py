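"""Significance filtering and the male/female ethanol-response comparison.

Loads the packaged 90-protein table of ethanol responses (males: 116:114,
females: 115:113), applies the |log2 R| > 1 fold-change criterion, and
partitions the two significant sets into shared / gender-specific proteins.
"""

from octofactor import SignificanceCriteria, datasets, overlap_analysis, significant_proteins

table = datasets.load_gender_table()
criteria = SignificanceCriteria()  # |log2 R| > 1, p < 0.05 where recorded

male = significant_proteins(table, "116:114", criteria)
female = significant_proteins(table, "115:113", criteria)
print(f"males:   {male.n} significant ({male.n_up} up, {male.n_down} down)")
print(f"females: {female.n} significant ({female.n_up} up, {female.n_down} down)")

report = overlap_analysis(male.table, female.table, "116:114", "115:113")
print(f"shared: {len(report.shared)}  male-only: {len(report.only_a)}  "
      f"female-only: {len(report.only_b)}")
for acc in report.opposite_direction:
    rec = table.get(acc)
    print(
        f"opposite direction: {rec.gene_symbol} "
        f"({rec.log2_ratio('116:114'):+.2f} in males, "
        f"{rec.log2_ratio('115:113'):+.2f} in females)"
    )
# The single opposite-direction protein is the folate-pathway enzyme FTCD —
# up with ethanol in males, down in females.
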