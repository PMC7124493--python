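"""Translate an implied graph into a DAG under reviewer criteria verdicts.

Every candidate pair is assessed in both directions: temporality, then
face-validity, then recourse to theory (never blocking), then a
counterfactual thought experiment.  Here the sex-exposure pair dies (sex
cannot precede the parental drinking history, and the reverse fails
face-validity), while the substance-use-exposure pair is *reversed* —
parental use causes offspring substance use, making substance use a mediator.
"""

from dagsynth import map_study, translate_graph
from dagsynth.fixtures import hypothetical_assessments, hypothetical_study
from dagsynth.io import export_dagitty

ig = map_study(hypothetical_study())
dag, log = translate_graph(ig, hypothetical_assessments())

print("translated DAG:")
print(export_dagitty(dag))
print("resolutions from the decision log:")
for entry in log.select(action="resolution"):
    v = entry.verdicts
    print(f"  {entry.subject}: {v['resolution']}  (posited {v['posited']})")
print(f"\ntotal decision-log entries: {len(log)}")

# The surviving 5 edges reproduce the study DAG; the deleted pair shows up
# only in the log, which is the point: absence of an edge is a recorded,
# justified decision.
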