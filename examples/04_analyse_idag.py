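"""Analyse the integrated DAG: what should the primary analysis adjust for?

Backdoor paths, minimal sufficient adjustment sets, the role of each
covariate, and the consequences of conditioning on the mediator.
"""

from dagsynth import (
    AnalysisGraph,
    adjustment_consequences,
    backdoor_paths,
    classify_covariate,
    minimal_adjustment_sets,
)
from dagsynth.fixtures import paper_fixtures

bundle = paper_fixtures()
ag = AnalysisGraph.from_mixed(bundle.final_idag)
x, y = bundle.focal

paths = backdoor_paths(ag, x, y)
print(f"backdoor paths {x} .. {y}: {len(paths)}")
sets = minimal_adjustment_sets(ag, x, y)
print(
    "minimal sufficient adjustment sets:",
    [sorted(s) for s in sorted(sets, key=len)],
)
for v in sorted(ag.digraph.nodes):
    if v in (x, y):
        continue
    print(f"role of {v}: {', '.join(classify_covariate(ag, x, y, v))}")

print("\nwhat if the analysis adjusted for the mediator?")
print(adjustment_consequences(ag, x, y, {"adol_substance"}))

# No backdoor path is open, so the empty set is the unique minimal adjustment
# set: the focal effect is unconfounded by any suggested covariate.
# Adjusting for adol_substance would remove part of the effect under study
# and open a collider path through it.
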