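"""Map a study's conclusions into its saturated implied graph.

The hypothetical study regressed adolescent alcohol use on historical
parental alcohol use, controlling for adolescent sex and substance use.
Mapping draws exposure->outcome, each control into both exposure and outcome
(the confounder reading of "controlled for"), then saturates: the remaining
control-control pair gets an edge with no direction yet.
"""

from dagsynth import map_study, roles_of
from dagsynth.fixtures import hypothetical_study
from dagsynth.graph import Orientation

record = hypothetical_study()
ig = map_study(record)

print(f"study: {record.study_id}")
print(f"nodes: {len(ig.nodes)}, edges after saturation: {len(ig.edges)}")
for e in sorted(ig.edges.values(), key=lambda e: sorted(e.pair)):
    if e.orientation is Orientation.UNASSIGNED:
        a, b = sorted(e.pair)
        print(f"  {a} -- {b}   (unassigned: direction decided at translation)")
    else:
        print(f"  {e.tail} -> {e.head}")
for nid in sorted(ig.nodes):
    print(f"role of {nid}: {', '.join(sorted(roles_of(ig, nid)))}")

# 6 edges on 4 nodes = saturated; the 5 directed ones encode the study's
# implied claims, the 1 unassigned pair is a claim not yet made either way.
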