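# dagsynth

Causal directed acyclic graphs (DAGs) decide what an epidemiological analysis
must adjust for, yet they are usually drawn ad hoc. **dagsynth** is a toolkit
for building them *systematically from the reviewed literature*, for
epidemiologists and evidence-synthesis teams who want every edge — and every
absent edge — to be a recorded, justified decision.

The workflow has three stages, each fully auditable through an append-only
decision log:

1. **Mapping.** Each study's conclusions become a saturated *implied graph*
   (IG): exposure → outcome; every control variable entered as a mutual cause
   of exposure and outcome (the confounder structure that "controlling for"
   presumes, since a control is a node that opens a backdoor path);
   mediators and instruments as the study concluded; and an undirected
   placeholder edge on every remaining pair. Saturation matters because *no*
   edge is the stronger causal claim — the method works backwards from a
   fully connected graph and only deletes what assessment rules out.
2. **Translation.** Every candidate edge is assessed in both directions under
   sequential causal criteria — temporality (cause precedes effect?),
   face-validity (plausible given the temporal order?), recourse to theory
   (formal support? never blocking: absence of theory is not absence of
   effect) — culminating in a counterfactual thought experiment in the
   potential-outcomes style. Each edge is retained as posited, reversed,
   noted bi-directional (both directions survive), or deleted.
3. **Integration.** Retained edges enter a provenance-bearing *directed edge
   index*; synthesis pours the index into a blank graph, yielding the
   *integrated DAG* (I-DAG) — identically, whatever the insertion order.
   Pairs made newly possible by combining studies are surfaced as *pending*
   and routed back through translation; equivalent nodes can be *recombined*
   (theory support, or identical in/out neighbourhoods).

The analysis layer then answers the question the DAG exists for, via the
backdoor criterion: a set `Z` identifies the effect of `X` on `Y` if `Z`
contains no descendant of `X` and blocks every path into `X`
(d-separation in the graph with `X`'s outgoing edges removed). dagsynth
enumerates backdoor paths, finds all minimal sufficient adjustment sets,
classifies each covariate (confounder / mediator / collider-on-path /
risk-factor-only / instrument-like), and reports the consequences of a
proposed conditioning set (over-control of mediated effect, induced collider
bias). Bi-directional edges are analysed as a latent common cause
`u ← L_uv → v`, with `L_uv` unmeasured and never eligible for adjustment.

## Worked example

Two studies of adolescent alcohol use ship as fixtures: a hypothetical study
of historical parental alcohol use (controls: adolescent sex, adolescent
substance use) and the Seljamo et al. follow-up study (early alcohol
initiation, family structure, adolescent sex). Running
`python examples/04_analyse_idag.py` builds both, translates them, synthesises
the I-DAG and prints:

```
backdoor paths parental_alc_hist .. adol_alc: 0
minimal sufficient adjustment sets: [[]]
role of adol_sex: risk_factor_only
role of adol_substance: mediator, collider_on_path
role of alc_initiation: mediator
role of family_structure: mediator

what if the analysis adjusted for the mediator?
conditioning set: {adol_substance}
over-control: blocks causal path parental_alc_hist -> adol_substance -> adol_alc
over-control: blocks causal path parental_alc_hist -> alc_initiation -> adol_substance -> adol_alc
collider bias: opens path parental_alc_hist -> adol_substance <- adol_sex -> adol_alc via adol_substance
collider bias: opens path parental_alc_hist -> adol_substance <- alc_initiation -> adol_alc via adol_substance
collider bias: opens path parental_alc_hist -> alc_initiation -> adol_substance <- adol_sex -> adol_alc via adol_substance
```

No backdoor path is open, so the empty set is the unique minimal sufficient
adjustment set: the focal effect is unconfounded by any suggested covariate.
Adolescent sex turns out to be a risk factor on another pathway (adjusting
may sharpen precision but removes no bias), while adjusting for adolescent
substance use would both remove part of the effect under study and induce
collider bias between the exposure and adolescent sex.

The other scripts under `examples/` walk one capability each: mapping,
translation with its decision log, index synthesis with pending-pair
re-assessment, and node recombination.

## Command line

A thin CLI wraps the same library:

```sh
dagsynth map study.yaml                      # implied graph as DOT
dagsynth translate study.yaml verdicts.csv   # DAG as DAGitty text
dagsynth index dag.dagitty my_study --index-csv index.csv
dagsynth synthesise --index-csv index.csv --exposure x --outcome y
dagsynth analyse idag.dagitty --exposure x --outcome y --adjust m
```

Study records are YAML documents (schema in
`schemas/study_record.schema.json`), assessments and the edge index are CSV,
graphs are DAGitty model text or DOT, and decision logs are newline-delimited
JSON. All exports are byte-stable across runs.

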