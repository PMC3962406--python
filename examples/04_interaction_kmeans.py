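"""K-means on the equal-expression deviation: which proteins does the knockout
pull away from their ethanol-only response?

Uses the packaged 45-protein table (K-means clusters 2 and 3 of the published
ethanol vs knockout+ethanol comparison). Distance from the identity line
E_a = E_b is |E_a - E_b|/sqrt(2); clusters are numbered by distance band.
"""

from octofactor import datasets, deviation_points, kmean_deviation, section_cluster_crosstab

table = datasets.load_interaction_table()
points = deviation_points(table, "116:114", "121:114")
result = kmean_deviation(points, k=3, seed=0)

print("cluster sizes:", result.cluster_sizes())
print("section x cluster crosstab:")
print(section_cluster_crosstab(points).to_string())

print("\nfarthest proteins from the equal-expression line:")
for p in sorted(points, key=lambda p: -p.distance)[:4]:
    rec = table.get(p.protein_id)
    print(f"  {rec.gene_symbol:8s} E={p.e_a:+.2f} KO+E={p.e_b:+.2f} "
          f"D={p.distance:.2f} ({p.section})")
# Cyp2e1 itself tops the list: strongly ethanol-induced, absent in the
# knockout — the knockout reverses the ethanol effect.
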