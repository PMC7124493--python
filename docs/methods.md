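# Methods

## The model

dagsynth operationalises a review workflow whose output is a causal DAG over
the variables of a research question, assembled from the conclusions of
individual reviewed studies rather than drawn free-hand. The underlying
graphical model is standard: nodes are variables (measured or unmeasured), a
directed edge asserts a causal effect, and the *absence* of an edge asserts
no effect — the stronger claim. The workflow therefore starts from
saturation (every pair connected) and only deletes edges that assessment
rules out.

Three graph stages are distinguished by an explicit flag on the container:

- **implied** — one study's saturated implied graph. Edges are *candidates*:
  directed where the study implies a direction, *unassigned* where only
  saturation put them there. Direction carries no commitment at this stage,
  so acyclicity is not enforced.
- **translated** — the study's DAG after criteria-based assessment. Every
  candidate must have been resolved (retained / reversed / bi-directional /
  deleted); unassigned leftovers are an error surfaced to the user, never
  silently dropped. Acyclicity of the directed retained subgraph is a hard
  invariant.
- **integrated** — the I-DAG synthesised from the cross-study edge index;
  same invariants as translated.

Edges live on *unordered* node pairs: "posited" and "reverse" are states of
one relationship, which is also the unit of assessment, so a pair can never
carry two edges. A relationship whose two directions both survive assessment
is stored as a single bi-directional edge. A DAG cannot contain a 2-cycle,
so bi-directional edges are excluded from cycle checking and expanded for
analysis into a latent common cause `u ← L_uv → v` — the standard graphical
reading of an association with credible effects in both directions. One
consequence worth noting: a translated graph consisting entirely of
bi-directional edges is legal (it encodes mutual latent confounding, not a
cycle).

## Translation semantics

Criteria run in a fixed order per direction: temporality, face-validity,
recourse to theory, counterfactual thought experiment. A `no` on temporality
or face-validity terminates the direction; recourse to theory never
terminates (absence of theory is not absence of effect — its slot exists to
force an explicit theory citation or its absence into the log); the
direction is retained only if the counterfactual verdict is `yes`. The
verdicts are reviewer input throughout: the tool records and resolves
judgments, it does not make them.

Two deliberate extensions where the procedure is silent:

- `temporality = unknown` (e.g. contemporaneous measurement) passes the
  criterion but forces the resulting edge's confidence to `low`. Deleting on
  ambiguity would invert the saturation principle, which treats deletion as
  the strongest claim.
- A translation may *defer* named pairs: the pair is removed from the
  candidate set, logged as deferred, and — because it is neither indexed nor
  registered as deleted — resurfaces as a pending pair at synthesis, to be
  assessed in the integrated context. This models reviews that postpone
  control–control relationships until the cross-study picture exists.

Resolutions are applied atomically after all pairs are assessed; if the
resolved edge set contains a directed cycle, translation fails with the
offending cycles listed. The tool never auto-deletes a reviewer-retained
edge to restore acyclicity — the conflict goes back to the reviewers.

## Index and synthesis

The directed edge index is the cross-study registry: one record per retained
relationship with direction, bi-directionality, worst-case confidence and
the set of contributing studies. Deletions are first-class entries with
their own provenance; without them "assessed and rejected" and "never
assessed" would be indistinguishable, and the pending-pair computation
(pending ∪ indexed ∪ deleted = all pairs) could not be exact. Index merge is
commutative, associative and idempotent. Studies that disagree on direction
are flagged as conflicts and block synthesis until re-assessed;
bi-directionality is a substantive claim, never a merge artifact.

Synthesis is a pure function of the index — the I-DAG equals the union of
indexed edges and their nodes, hence insertion-order invariance holds by
construction and is verified, not assumed, in the test suite. Reviewer-added
nodes enter with a dedicated role and generate one pending pair per existing
node; a node left isolated after assessment triggers a warning, since a
variable that influences fewer than two others does not meet the inclusion
rule.

Recombination merges two non-adjacent nodes when theory flags them as
categories of one concept or their in/out neighbourhoods (excluding each
other) coincide. Merged edges union provenance and aliases and take
worst-case (`low` wins) confidence — the merged claim is only as strong as
its weakest constituent. Merges that would create a self-loop,
contradictory directions or a cycle are refused.

## Analysis layer

d-separation uses networkx's reachability-based `is_d_separator`; the test
suite and the acceptance script cross-check it against an independent
hand-written oracle that enumerates every undirected-sense path and applies
the per-path blocking rules literally. Adjustment sets use the classic
backdoor criterion (no descendants of the exposure; d-separation with the
exposure's outgoing edges removed), not the generalized adjustment
criterion — a deliberate simplification matching the workflow's framing and
keeping the subset-enumeration oracle exact; it is the natural extension
point. The search is exhaustive over measured non-descendant nodes and is
capped at 20 candidates with an explicit failure message; reviewed-literature
graphs sit well under this, and a branch-and-bound search would be the
upgrade path for larger I-DAGs.

Covariate classification reports *all* applicable roles in a fixed order
(mediator, confounder, collider-on-path, then risk-factor-only /
instrument-like / disconnected), because a node genuinely can be, e.g., both
a mediator and a collider on a non-causal path — exposure-induced
mediator–outcome confounding being the canonical case. Ranking such roles is
an analytic decision left to the user.

## Fixtures and what they do (and do not) show

The shipped fixtures encode the two worked example studies — a hypothetical
study of historical parental alcohol use on adolescent alcohol use with
adolescent sex and substance use as controls, and the Seljamo et al. study
adding early alcohol initiation and family structure. Verdicts stated by the
worked narrative (the temporality failure of substance-use → parental-use,
the face-validity failure of parental-use → sex, the rejection of family
structure vs sex and the retention of initiation → substance use at the
integrated stage, the unconfounded focal pair) are encoded directly;
verdicts the narrative only implies are marked `inferred` in their
rationale, so tests that depend only on stated facts are separable from
tests that depend on fixture choices. The family-structure–sex pair is
deferred from the Seljamo translation precisely so that it is assessed in
the integrated context, as the narrative describes.

The random generators define the property-test conditions: DAGs of 2–12
nodes with independent edge probability along a random topological order,
and complete random assessment sets with configurable retention probability
(default 0.5 retained per direction, 0.05 bi-directional, 5% of retained
temporality verdicts `unknown`), redrawn with a 0.9 retention back-off when
a draw would induce a directed cycle. These exercise the machinery over the
full combinatorial space at desk scale (oracle checks exhaust all
conditioning subsets up to 7 nodes — 500 graphs in the acceptance script);
they do not emulate the texture of a real review: correlated verdicts across
related pairs, reviewer disagreement, or the much larger, sparser I-DAGs of
a full literature. Passing tests show the machinery is exact, not that any
particular substantive DAG is right.

## Numerical and formatting choices

- All randomness is `random.Random(seed)`-driven; same seed, same output.
- Exports (DAGitty, DOT, CSV, log) order nodes and edges lexicographically
  and are byte-identical across runs. Decision-log timestamps come from an
  injectable clock defaulting to the empty string; the CLI fills wall-clock
  time only on request, keeping audit artifacts diffable.
- DAGitty import accepts layout coordinates and unknown annotations and
  records them as notices; export emits structure only.
- Unassigned pairs take the first-assessed direction as "posited"; the
  resolution semantics make the choice immaterial up to relabelling.
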