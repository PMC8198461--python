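"""Preranked GSEA of the planted signatures.

Ranks genes by the moderated t from the treated-vs-control comparison and
tests the three planted sets with the gene-permutation null. The MAPK-like
set should be negatively enriched (treatment shuts the pathway down) and
the TD-like set positively enriched (redifferentiation).
"""

from thyrosig import (
    SyntheticConfig,
    differential_expression,
    gsea_preranked,
    make_synthetic_signatures,
    rank_genes,
    simulate_experiment,
)

config = SyntheticConfig(seed=1)
signatures = make_synthetic_signatures(config)
expr, ann = simulate_experiment(config, signatures)

de = differential_expression(expr, ann, "Dabrafenib", "DMSO")
ranked = rank_genes(de)
result = gsea_preranked(ranked, signatures, n_perm=2000, min_size=15, max_size=500, seed=1)
print(result.round(4))
# nes < 0 with small fdr = coordinated downregulation of the set;
# p_perm is bounded below by 1/(n_same_sign_permutations + 1).
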