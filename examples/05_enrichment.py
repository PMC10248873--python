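"""Is a differential gene set enriched for a functional category?

Tests a 12-gene query against three gene-set collections in a 60-gene
universe with the hypergeometric upper-tail test and Benjamini-Hochberg
adjustment.  'spermatogenesis' was constructed to share 6 of its 10
genes with the query; the q-value column is what survives multiple
testing across the three collections.
"""

from meripscore import hypergeom_enrich

universe = [f"gene{i:02d}" for i in range(60)]
query = set(universe[:12])
collections = {
    "spermatogenesis": set(universe[6:16]),     # 6 of 10 members in the query
    "rna_methylation": set(universe[10:30]),    # 2 of 20 members in the query
    "housekeeping": set(universe[40:55]),       # no overlap
}

table = hypergeom_enrich(query, collections, universe)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\np_value = P(X >= k) under Hypergeometric(N, K, n); q_value = BH-adjusted.")
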