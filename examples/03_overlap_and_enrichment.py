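"""Intersecting gene lists and hypergeometric over-representation analysis.

Takes a study list (think: TWAS-significant genes overlapping the DEGs),
and tests annotation sets for enrichment against the weight-panel universe.
"""

from twaskit import GeneSetCatalog, hypergeom_ora, intersect_genes, simulate_gene_sets

universe = [f"G{i:05d}" for i in range(1, 501)]

twas_hits = set(universe[:40])
deg_hits = set(universe[25:80])
common = intersect_genes(twas_hits, deg_hits)
print(f"{len(common)} genes shared by the two screens: {common[:8]} ...")

# catalog whose first set oversamples the front of the universe ordering
sets = simulate_gene_sets(
    30, (10, 40), universe, enriched_sets={"TERM_X": (60, 0.8)}, seed=3
)
catalog = GeneSetCatalog(sets=sets, universe=universe)
ora = hypergeom_ora(twas_hits, catalog, min_set_size=5)
print(ora.nsmallest(5, "pvalue")[["ID", "k", "K", "n", "N", "pvalue", "p.adjust"]].round(6))
# p is the hypergeometric upper tail P[X >= k]: the chance a random n-gene
# draw from the N-gene universe overlaps the K-gene set at least k times.
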