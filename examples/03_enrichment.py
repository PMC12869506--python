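"""Hypergeometric enrichment: disease categories, ORA and term overlap.

Uses the packaged 26-gene module category table to reproduce the module's
epilepsy-gene enrichment against its 320-gene source network, runs an ORA
on a synthetic GMT collection with one planted term, and tests the overlap
of two enriched-term lists.
"""

from comodmap import (
    GeneCategoryTable,
    category_enrichment,
    load_module26_categories,
    ora,
    simulate_gene_sets,
    term_overlap_test,
)

# --- module vs network disease-gene enrichment -------------------------------
module26 = load_module26_categories()
print(f"module: {len(module26)} genes, "
      f"{module26.percent_positive()}% epilepsy-associated")

# the source network: 31 epilepsy + 22 epilepsy-related among 320 genes
network = GeneCategoryTable({
    f"g{i}": ("epilepsy" if i < 31 else "epilepsy_related" if i < 53 else "none")
    for i in range(320)
})
module = [f"g{i}" for i in range(13)] + [f"g{i}" for i in range(53, 66)]
res = category_enrichment(module, network.genes, network)
print(f"enrichment: k={res.k}/{res.n} vs K={res.K}/{res.N}, "
      f"fold={res.fold:.2f}, p={res.p:.3g}")

# --- ORA with a planted term -------------------------------------------------
universe = {f"u{i:04d}" for i in range(2000)}
target = {f"u{i:04d}" for i in range(40)}
coll = simulate_gene_sets(universe, 50, (20, 80),
                          planted=[("PLANTED", target, 0.8)], seed=2)
table = ora(target, coll, alpha=0.05)
best = table.iloc[0]
print(f"ORA: top term {best.term_id}, k={best.k}/{best.n}, "
      f"fold={best.fold:.1f}, FDR={best.fdr:.2e}")

# --- overlap of two enriched-term lists --------------------------------------
p = term_overlap_test(n_terms_a=449, n_terms_b=367, overlap=155, universe_size=27047)
print(f"term-overlap p = {p:.3g}  (155 shared of 449 vs 367 in 27,047)")
# The enrichment p is the upper-tail hypergeometric probability; fold is
# (k/n)/(K/N).  The overlap p far below 0.001 shows the two term lists share
# many more terms than chance.
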