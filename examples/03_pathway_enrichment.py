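"""Hypergeometric pathway enrichment with FDR and redundancy pruning.

Tests candidate genes against gene sets drawn over the library universe,
adjusts p-values by Benjamini-Hochberg, and prunes sets whose candidate
members are more than 50% covered by better-ranked kept sets.
"""

from slscreen.enrichment import enrich, results_to_frame
from slscreen.io import GeneSet, GeneSetCollection

universe = {f"G{i:03d}" for i in range(200)}
candidates = {f"G{i:03d}" for i in range(12)}  # 12 of 200 genes called

collection = GeneSetCollection((
    GeneSet("PATHWAY_HIT", "", frozenset(f"G{i:03d}" for i in range(8))),
    GeneSet("PATHWAY_SUB", "", frozenset(f"G{i:03d}" for i in range(4))),
    GeneSet("PATHWAY_HALF", "", frozenset({"G006", "G007", "G008", "G009"})),
    GeneSet("PATHWAY_COLD", "", frozenset(f"G{i:03d}" for i in range(100, 140))),
))

results = enrich(candidates, collection, universe)
print(results_to_frame(results).drop(columns="candidate_members").to_string(index=False))
# PATHWAY_SUB is pruned (kept=0): its candidate members are fully
# covered by the better-ranked PATHWAY_HIT.  PATHWAY_HALF survives: only
# 2 of its 4 candidate members are already covered, i.e. exactly 50%,
# and only "more than 50%" removes.  k of K set members are among the n
# candidates drawn from the N-gene universe; q is the BH-adjusted p.
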