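"""Gene-set over-representation of differentially methylated genes.

Maps significant probes to their annotated genes, builds a synthetic
GMT collection, and tests each term with the hypergeometric upper tail.
"""

import numpy as np

import ewaskit as ek

matrix, sheet, annotation, truth = ek.simulate_ewas_dataset(
    n_samples=120, n_probes=2000, n_causal=15, effect_size=0.5, seed=7
)
spec = ek.ModelSpec(model="glm", exposure="exposure", covariates=["age"])
table = ek.run_dmp(matrix, sheet, spec, annotation)

sig_genes, universe = ek.map_sites_to_genes(table, "fdr<0.05")
print(f"significant genes: {len(sig_genes)} of a {len(universe)}-gene universe")

# synthetic GMT: term T000 is enriched for the significant genes
rng = np.random.default_rng(0)
gene_sets = {"T000": ("planted term",
                      set(sorted(sig_genes)[:8]) | set(rng.choice(sorted(universe), 6)))}
for t in range(1, 20):
    gene_sets[f"T{t:03d}"] = (f"random term {t}",
                              set(rng.choice(sorted(universe), rng.integers(10, 30))))

result = ek.overrepresentation_test(sig_genes, universe, gene_sets, min_size=5)
print("\ntop terms (k/K = significant/universe genes in term):")
print(result.head(4)[["term_id", "term_name", "k", "K", "p", "adj_p"]]
      .to_string(index=False))
# The planted term should rank first with a small BH-adjusted p; random
# terms should sit near p = 1.
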