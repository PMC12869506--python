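"""Expand a human gene list into a fly ortholog catalog.

Builds an ortholog score table with the published mapping composition (163
one-to-one genes, 37 human genes collapsing onto 17 fly genes, 31 human
genes fanning out to 107 tied fly partners), filters at the default score
threshold of 3, and expands to the unique fly-gene catalog.
"""

from comodmap import classify_and_expand, filter_by_score, simulate_ortholog_table

table = simulate_ortholog_table(
    one_to_one=163, many_to_one=(37, 17), one_to_many=(31, 107), min_score=3, seed=0
)
print(f"ortholog table: {len(table)} scored human->fly pairs")

catalog = classify_and_expand(filter_by_score(table, min_score=3), tie_window=1)
print(f"catalog: {len(catalog)} unique fly genes")
for category, count in catalog.category_counts().items():
    print(f"  {category}: {count}")
# 163 + 17 + 107 = 287 unique fly genes: the catalog size a score-threshold
# of 3 and a one-point tie window produce from this composition.
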