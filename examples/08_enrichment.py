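"""Hypergeometric over-representation of a gene list against gene sets."""

from rewirenet import enrichment, synthgen

universe = [f"G{i:03d}" for i in range(200)]
query = universe[:15]  # pretend these are the DEGs

# the first simulated set is forced to overlap the head of the gene list
sets = synthgen.simulate_genesets(universe, n_sets=8, set_size=20,
                                  enriched_set_overlap=10, seed=8)
collection = enrichment.GeneSetCollection(sets=sets)

table = enrichment.hypergeom_enrich(query, universe, collection,
                                    min_size=5, max_size=100)
print(table[["set", "overlap", "set_size", "p", "fdr"]]
      .round(6).to_string(index=False))
# GS000 was built to share 10 genes with the query: its upper-tail
# hypergeometric p (and BH FDR) is many orders below the random sets.
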