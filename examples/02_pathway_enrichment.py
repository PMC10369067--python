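"""Over-representation analysis of a gene list against pathway sets.

The statistic is the exact hypergeometric upper tail (one-sided Fisher
test); Benjamini-Hochberg adjusted p-values are reported alongside, and
Reactome-style results are narrowed to topmost sets with layout.
"""

from mapforge.enrichment import (
    GeneSet,
    enrich_collection,
    filter_reactome,
    ora_p_value,
)

query = ["RHO", "RP1", "PRPH2", "PRPF31", "CNGA1"]
sets = {
    "phototransduction": GeneSet(
        "phototransduction", "Visual phototransduction",
        frozenset(["RHO", "RP1", "PRPH2", "CNGA1", "GNAT1", "PDE6B"]),
        collection="reactome",
    ),
    "splicing": GeneSet(
        "splicing", "mRNA splicing",
        frozenset(["PRPF31", "PRPF8", "SNRNP200", "SF3B1"]),
        collection="reactome", parent_id="phototransduction",
    ),
    "decoy": GeneSet(
        "decoy", "Unrelated pathway",
        frozenset(["TP53", "MDM2", "CDKN1A", "ATM"]),
        collection="reactome",
    ),
}

results = enrich_collection(query, list(sets.values()), max_results=5)
for r in results:
    print(f"rank {r.rank}: {r.set_id}  overlap {r.overlap}/{r.set_size}  "
          f"p={r.p_value:.3g}  adj_p={r.adjusted_p:.3g}")

filtered = filter_reactome(results, sets)
print("after layout/topmost constraints:", [r.set_id for r in filtered])

print("worked tail example P(X>=3 | K=4, n=3, N=10) =",
      ora_p_value(3, 4, 3, 10))
# Lower p means the overlap between the query and the set is less likely
# under random draws from the universe; the topmost-ancestor rule keeps
# "phototransduction" and drops its enriched descendant "splicing".
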