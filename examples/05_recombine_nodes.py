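"""Recombine equivalent nodes to keep a growing integrated DAG tractable.

Two controls that send edges to exactly the same nodes (identical in/out
neighbourhoods) are structural duplicates — e.g. parental monitoring and
autonomy granting as categories of parenting practice.  Merging them unions
edges, provenance and aliases, and is refused if it would create a cycle.
"""

from dagsynth import MixedGraph, NodeRef, recombination_candidates, recombine
from dagsynth.graph import Status
from dagsynth.log import DecisionLog

g = MixedGraph()
for nid in ("parental_monitoring", "autonomy_granting", "parental_alc_hist", "adol_alc"):
    g.add_node(nid)
for c in ("parental_monitoring", "autonomy_granting"):
    g.add_edge(c, "parental_alc_hist", status=Status.RETAINED)
    g.add_edge(c, "adol_alc", status=Status.RETAINED)
g.add_edge("parental_alc_hist", "adol_alc", status=Status.RETAINED)

print("recombination candidates:")
for pair, evidence in recombination_candidates(g):
    print(f"  {pair[0]} + {pair[1]}   evidence: {', '.join(sorted(evidence))}")

log = DecisionLog()
merged = recombine(
    g,
    ("autonomy_granting", "parental_monitoring"),
    NodeRef(id="parenting_practice"),
    "both are categories of parenting practice",
    log=log,
)
print(f"\nafter merge: {sorted(merged.nodes)}")
print(f"aliases kept on the merged node: {sorted(merged.nodes['parenting_practice'].aliases)}")
print(f"log: {next(log.select(stage='recombination')).rationale}")

# The merged node inherits both edge fans; downstream reachability among the
# untouched nodes is unchanged because the pair had identical neighbourhoods.
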