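"""Pathway-level concordance between two differential analyses.

Builds a toy gene universe with themed gene sets, runs Fisher-exact
over-representation on the up- and down-regulated gene lists of two
analyses, and quantifies their agreement over the shared pathway
universe with Cohen's kappa and an odds ratio.
"""

from cgsc import ora_enrichment, pathway_agreement

universe = [f"g{i:03d}" for i in range(300)]
gene_sets = {
    # two "stemness" and two "immune" sets plus neutral bystanders
    "stemness_core": set(universe[0:20]),
    "lineage_spec": set(universe[15:40]),
    "antigen_presentation": set(universe[40:60]),
    "interferon_response": set(universe[55:80]),
    **{f"bystander_{i}": set(universe[80 + 10 * i: 95 + 10 * i]) for i in range(10)},
}

# both analyses up-regulate stemness genes and down-regulate immune genes,
# with mild disagreement at the margins
analysis = {
    "tumor c-GSC": (set(universe[0:35]), set(universe[42:75])),
    "in vitro ic-GSC": (set(universe[5:38]), set(universe[40:70])),
}

enriched = {}
for name, (up, down) in analysis.items():
    hits = set()
    for direction, query in (("up", up), ("down", down)):
        table = ora_enrichment(query, gene_sets, universe)
        for pathway in table.index[table["q"] < 0.05]:
            hits.add(pathway)
            print(f"{name:16s} {direction:4s} {pathway:22s} "
                  f"OR={table.loc[pathway, 'odds_ratio']:.1f} q={table.loc[pathway, 'q']:.2e}")
    enriched[name] = hits

result = pathway_agreement(
    enriched["tumor c-GSC"], enriched["in vitro ic-GSC"], gene_sets.keys()
)
print()
print(f"2x2 table over {result.n} pathways: a={result.a} b={result.b} "
      f"c={result.c} d={result.d}")
print(f"kappa = {result.kappa:.3f}, OR = {result.odds_ratio:.1f}, "
      f"Fisher p = {result.fisher_p:.2e}")
# kappa near 1 means the two analyses activate and repress the same
# pathways far beyond what their marginal hit rates would give by chance.
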