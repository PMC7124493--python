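"""Sequential causal criteria, per-edge resolution and whole-graph translation."""

import itertools

import pytest

from dagsynth.graph import Confidence, CycleError, MixedGraph, Orientation, Stage, Status
from dagsynth.log import DecisionLog
from dagsynth.translation import (
    AssessmentError,
    CriteriaAssessment,
    DirectionOutcome,
    DirectionResult,
    Resolution,
    assess_direction,
    replay,
    resolve_edge,
    translate_graph,
)


def A(tail, head, criterion, verdict, **kw):
    return CriteriaAssessment(
        study_id="s", tail=tail, head=head, criterion=criterion, verdict=verdict, **kw
    )


class TestAssessDirection:
    def test_temporality_failure_stops_sequence(self):
        # an adolescent's substance use cannot precede historical parental use
        result = assess_direction(
            [A("adol_substance", "parental_alc_hist", "temporality", "no")]
        )
        assert result.outcome is DirectionOutcome.FAILED_TEMPORALITY

    def test_face_validity_failure_after_temporal_pass(self):
        result = assess_direction(
            [
                A("parental_alc_hist", "adol_sex", "temporality", "yes"),
                A("parental_alc_hist", "adol_sex", "face_validity", "no"),
            ]
        )
        assert result.outcome is DirectionOutcome.FAILED_FACE_VALIDITY

    def test_absent_theory_does_not_block_retention(self):
        result = assess_direction(
            [
                A("adol_sex", "adol_alc", "temporality", "yes"),
                A("adol_sex", "adol_alc", "face_validity", "yes"),
                A("adol_sex", "adol_alc", "recourse_to_theory", "unknown"),
                A("adol_sex", "adol_alc", "counterfactual", "yes"),
            ]
        )
        assert result.outcome is DirectionOutcome.RETAINED
        assert not result.low_confidence

    def test_counterfactual_no_fails(self):
        result = assess_direction(
            [
                A("a", "b", "temporality", "yes"),
                A("a", "b", "face_validity", "yes"),
                A("a", "b", "recourse_to_theory", "no"),
                A("a", "b", "counterfactual", "no"),
            ]
        )
        assert result.outcome is DirectionOutcome.FAILED_COUNTERFACTUAL

    def test_temporality_unknown_passes_with_low_confidence(self):
        result = assess_direction(
            [
                A("a", "b", "temporality", "unknown"),
                A("a", "b", "face_validity", "yes"),
                A("a", "b", "recourse_to_theory", "yes"),
                A("a", "b", "counterfactual", "yes"),
            ]
        )
        assert result.outcome is DirectionOutcome.RETAINED
        assert result.low_confidence

    def test_unknown_forbidden_outside_theory_and_temporality(self):
        with pytest.raises(AssessmentError):
            A("a", "b", "face_validity", "unknown")
        with pytest.raises(AssessmentError):
            A("a", "b", "counterfactual", "unknown")

    @pytest.mark.parametrize(
        "batch",
        [
            # out of order
            [("face_validity", "yes"), ("temporality", "yes")],
            # gap: skips face validity
            [("temporality", "yes"), ("recourse_to_theory", "yes")],
            # continues past a failed criterion
            [("temporality", "no"), ("face_validity", "yes")],
            # incomplete: stops before the counterfactual without failing
            [("temporality", "yes"), ("face_validity", "yes")],
            # duplicated criterion
            [("temporality", "yes"), ("temporality", "yes")],
        ],
    )
    def test_malformed_sequences_rejected(self, batch):
        with pytest.raises(AssessmentError):
            assess_direction([A("a", "b", c, v) for c, v in batch])

    def test_pure_function_of_input(self):
        batch = [
            A("a", "b", "temporality", "yes"),
            A("a", "b", "face_validity", "yes"),
            A("a", "b", "recourse_to_theory", "yes"),
            A("a", "b", "counterfactual", "yes"),
        ]
        assert assess_direction(batch) == assess_direction(list(batch))


OUTCOMES = list(DirectionOutcome)


class TestResolveEdge:
    @pytest.mark.parametrize(
        "posited,reverse", list(itertools.product(OUTCOMES, OUTCOMES))
    )
    def test_truth_table(self, posited, reverse):
        """retained/retained -> bidirectional; one retained -> that direction;
        neither -> delete — checked over all 16 outcome combinations."""
        res = resolve_edge(
            DirectionResult(("a", "b"), posited), DirectionResult(("b", "a"), reverse)
        )
        p = posited is DirectionOutcome.RETAINED
        r = reverse is DirectionOutcome.RETAINED
        expected = {
            (True, True): Resolution.BIDIRECTIONAL,
            (True, False): Resolution.RETAIN_POSITED,
            (False, True): Resolution.REVERSE,
            (False, False): Resolution.DELETE,
        }[(p, r)]
        assert res is expected

    @pytest.mark.parametrize(
        "posited,reverse", list(itertools.product(OUTCOMES, OUTCOMES))
    )
    def test_symmetry_under_argument_swap(self, posited, reverse):
        a = DirectionResult(("a", "b"), posited)
        b = DirectionResult(("b", "a"), reverse)
        swap = {
            Resolution.RETAIN_POSITED: Resolution.REVERSE,
            Resolution.REVERSE: Resolution.RETAIN_POSITED,
            Resolution.BIDIRECTIONAL: Resolution.BIDIRECTIONAL,
            Resolution.DELETE: Resolution.DELETE,
        }
        assert resolve_edge(b, a) is swap[resolve_edge(a, b)]

    def test_missing_direction_is_an_error(self):
        with pytest.raises(AssessmentError):
            resolve_edge(DirectionResult(("a", "b"), DirectionOutcome.RETAINED), None)


class TestTranslateGraph:
    def test_worked_example_translation(self, bundle):
        """The hypothetical study's DAG: the focal edge survives, substance
        use becomes a mediator fed by the exposure, sex feeds outcome and
        substance use, and the sex-exposure pair is deleted (sex is a risk
        factor on another pathway, not a confounder)."""
        dag = bundle.translated["hypothetical"]
        assert dag.stage is Stage.TRANSLATED
        assert {(e.tail, e.head) for e in dag.edges.values()} == {
            ("parental_alc_hist", "adol_alc"),
            ("parental_alc_hist", "adol_substance"),
            ("adol_sex", "adol_alc"),
            ("adol_sex", "adol_substance"),
            ("adol_substance", "adol_alc"),
        }
        assert dag.edge("adol_sex", "parental_alc_hist") is None
        assert dag.is_acyclic()
        assert all(e.status is Status.RETAINED for e in dag.edges.values())

    def test_graph_without_candidates_translates_vacuously(self):
        g = MixedGraph()
        g.add_node("a")
        g.add_node("b")
        g.add_edge("a", "b", status=Status.RETAINED)
        out, log = translate_graph(g, [])
        assert out.equivalent(g)
        assert len(log) == 0

    def test_retained_cycle_reported_not_silently_fixed(self):
        g = MixedGraph()
        for nid in "abc":
            g.add_node(nid)
        g = g.saturate()
        assessments = []
        for t, h in [("a", "b"), ("b", "c"), ("c", "a")]:
            assessments += [
                A(t, h, "temporality", "yes"),
                A(t, h, "face_validity", "yes"),
                A(t, h, "recourse_to_theory", "yes"),
                A(t, h, "counterfactual", "yes"),
            ]
            assessments.append(A(h, t, "temporality", "no"))
        with pytest.raises(CycleError) as err:
            translate_graph(g, assessments)
        assert err.value.cycles

    def test_unresolved_candidate_pair_is_an_error(self):
        g = MixedGraph()
        for nid in "ab":
            g.add_node(nid)
        g = g.saturate()
        with pytest.raises(AssessmentError):
            translate_graph(g, [])

    def test_temporality_unknown_forces_low_edge_confidence(self):
        g = MixedGraph()
        g.add_node("a")
        g.add_node("b")
        g = g.saturate()
        assessments = [
            A("a", "b", "temporality", "unknown"),
            A("a", "b", "face_validity", "yes"),
            A("a", "b", "recourse_to_theory", "unknown"),
            A("a", "b", "counterfactual", "yes"),
            A("b", "a", "temporality", "no"),
        ]
        dag, _ = translate_graph(g, assessments)
        assert dag.edge("a", "b").confidence is Confidence.LOW

    def test_bidirectional_resolution_stored_as_single_edge(self):
        g = MixedGraph()
        g.add_node("a")
        g.add_node("b")
        g = g.saturate()
        assessments = []
        for t, h in [("a", "b"), ("b", "a")]:
            assessments += [
                A(t, h, "temporality", "yes"),
                A(t, h, "face_validity", "yes"),
                A(t, h, "recourse_to_theory", "yes"),
                A(t, h, "counterfactual", "yes"),
            ]
        dag, _ = translate_graph(g, assessments)
        assert len(dag.edges) == 1
        assert dag.edge("a", "b").orientation is Orientation.BIDIRECTIONAL


class TestDecisionLog:
    def test_every_resolution_logged_with_criterion_trail(self, bundle):
        """Each candidate pair yields one resolution entry plus one entry per
        criterion verdict; early-stopped directions carry a skip marker."""
        log = bundle.log
        resolutions = list(log.select(stage="translation", action="resolution"))
        # hypothetical: 6 pairs; seljamo: 9 assessed (1 deferred); idag: 3
        assert len(resolutions) == 18
        criterion_entries = list(log.select(stage="translation", action="criterion"))
        total_assessments = (
            len(bundle.assessments["hypothetical"])
            + len(bundle.assessments["seljamo_2006"])
            + len(bundle.idag_assessments)
        )
        assert len(criterion_entries) == total_assessments
        skips = list(log.select(stage="translation", action="criteria_skipped"))
        assert skips and all("earlier criterion failed" in e.rationale for e in skips)
        deferrals = list(log.select(stage="translation", action="deferred"))
        assert [e.subject for e in deferrals] == ["adol_sex -- family_structure"]

    def test_sequence_numbers_strictly_increase(self, bundle):
        seqs = [e.seq for e in bundle.log]
        assert seqs == list(range(1, len(seqs) + 1))

    def test_replay_reproduces_translated_graph(self, bundle):
        ig = bundle.implied["hypothetical"]
        sub_log = DecisionLog()
        dag, sub_log = translate_graph(
            ig, bundle.assessments["hypothetical"], log=sub_log
        )
        replayed = replay(ig, sub_log)
        assert replayed.equivalent(dag)

    def test_replay_reproduces_deferred_translation(self, bundle):
        ig = bundle.implied["seljamo_2006"]
        sub_log = DecisionLog()
        dag, sub_log = translate_graph(
            ig,
            bundle.assessments["seljamo_2006"],
            log=sub_log,
            defer=bundle.defer["seljamo_2006"],
        )
        assert replay(ig, sub_log).equivalent(dag)
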