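"""Edge index semantics, I-DAG synthesis, pending accounting, recombination."""

import itertools
import random

import networkx as nx
import pytest

from dagsynth.graph import (
    Confidence,
    GraphError,
    MixedGraph,
    NodeRef,
    Orientation,
    Stage,
    Status,
)
from dagsynth.integration import (
    DirectedEdgeRecord,
    EdgeIndex,
    add_reviewer_node,
    index_edges,
    pending_pairs,
    recombination_candidates,
    recombine,
    resolve_pending,
    synthesise,
)
from dagsynth.fixtures import RandomGraphSpec, random_dag
from dagsynth.log import DecisionLog


def one_edge_dag(tail="x", head="y"):
    g = MixedGraph(stage=Stage.TRANSLATED)
    g.add_node(tail)
    g.add_node(head)
    g.add_edge(tail, head, status=Status.RETAINED)
    return g


class TestIndex:
    def test_indexing_records_retained_edges_with_provenance(self, bundle):
        rec = bundle.index.records[frozenset({"parental_alc_hist", "adol_alc"})]
        assert (rec.tail, rec.head) == ("parental_alc_hist", "adol_alc")
        assert rec.provenance == {"hypothetical", "seljamo_2006"}

    def test_reindexing_same_dag_is_idempotent(self):
        dag = one_edge_dag()
        idx = index_edges(dag, "s1")
        again = index_edges(dag, "s1", index=idx)
        assert len(again.records) == 1
        assert again.records[frozenset({"x", "y"})].provenance == {"s1"}

    def test_direction_conflict_flagged_not_merged(self):
        """Study A retains x->y, study B retains y->x: neither wins and the
        pair is queued for re-assessment rather than becoming bidirectional."""
        idx = index_edges(one_edge_dag("x", "y"), "a")
        idx = index_edges(one_edge_dag("y", "x"), "b", index=idx)
        assert frozenset({"x", "y"}) in idx.conflicts
        assert idx.records[frozenset({"x", "y"})].provenance == {"a"}
        with pytest.raises(GraphError, match="conflict"):
            synthesise(idx)

    def test_merge_commutative_and_idempotent(self):
        a = index_edges(one_edge_dag("x", "y"), "a")
        b = EdgeIndex()
        b.add_record(DirectedEdgeRecord("x", "y", provenance=frozenset({"b"})))
        b.register_deletion(("x", "z"), "b")
        ab, ba = a.merge(b), b.merge(a)
        assert ab.records == ba.records and ab.deletions == ba.deletions
        assert ab.merge(ab).records == ab.records
        assert ab.records[frozenset({"x", "y"})].provenance == {"a", "b"}

    def test_merged_confidence_is_worst_case(self):
        idx = EdgeIndex()
        idx.add_record(DirectedEdgeRecord("x", "y", provenance=frozenset({"a"})))
        idx.add_record(
            DirectedEdgeRecord(
                "x", "y", confidence=Confidence.LOW, provenance=frozenset({"b"})
            )
        )
        assert idx.records[frozenset({"x", "y"})].confidence is Confidence.LOW

    def test_untranslated_graph_rejected(self):
        g = MixedGraph(stage=Stage.IMPLIED)
        with pytest.raises(GraphError):
            index_edges(g, "s")

    def test_deletion_and_record_disjoint(self):
        idx = index_edges(one_edge_dag(), "s")
        with pytest.raises(GraphError):
            idx.register_deletion(("x", "y"), "s")


class TestSynthesise:
    def test_single_record_index_gives_that_edge_and_no_pending(self):
        idx = index_edges(one_edge_dag(), "s")
        idag, pending = synthesise(idx)
        assert {(e.tail, e.head) for e in idag.edges.values()} == {("x", "y")}
        assert idag.stage is Stage.INTEGRATED
        assert pending == []

    def test_worked_example_pending_pairs(self, bundle):
        """Synthesis surfaces exactly the relationships made newly possible
        by combining the two studies."""
        assert ("adol_sex", "family_structure") in bundle.pending
        assert ("adol_substance", "alc_initiation") in bundle.pending
        assert len(bundle.pending) == 3

    def test_worked_example_pending_resolution(self, bundle):
        """Reviewer verdicts reject family structure vs sex but retain early
        initiation as a cause of other substance use."""
        final = bundle.final_idag
        assert final.edge("adol_sex", "family_structure") is None
        e = final.edge("alc_initiation", "adol_substance")
        assert (e.tail, e.head) == ("alc_initiation", "adol_substance")
        assert final.is_acyclic()

    @pytest.mark.parametrize("seed", range(12))
    def test_insertion_order_invariance(self, seed):
        """Any permutation of index insertions yields the same I-DAG."""
        dag = random_dag(RandomGraphSpec(3 + seed % 5, 0.7, 7000 + seed))
        edges = [(e.tail, e.head) for e in dag.directed_edges()]
        if not edges:
            return
        rng = random.Random(seed)
        reference = None
        perms = (
            list(itertools.permutations(edges))
            if len(edges) <= 4
            else [rng.sample(edges, len(edges)) for _ in range(20)]
        )
        for perm in perms:
            idx = EdgeIndex()
            for t, h in perm:
                idx.add_record(DirectedEdgeRecord(t, h, provenance=frozenset({"s"})))
            idag, _ = synthesise(idx)
            if reference is None:
                reference = idag
            else:
                assert idag.equivalent(reference)

    def test_pending_accounting_is_exact(self, bundle):
        """pending + indexed + deleted pairs exactly tile all node pairs."""
        idag, index = bundle.idag, bundle.index
        n = len(idag.nodes)
        all_pairs = {
            frozenset(p) for p in itertools.combinations(sorted(idag.nodes), 2)
        }
        pend = {frozenset(p) for p in pending_pairs(idag, index)}
        recorded = set(index.records)
        deleted = set(index.deletions)
        assert pend | recorded | deleted == all_pairs
        assert not (pend & recorded) and not (pend & deleted) and not (recorded & deleted)
        assert len(all_pairs) == n * (n - 1) // 2

    def test_cyclic_union_reported_with_cycles(self):
        idx = EdgeIndex()
        for t, h in [("a", "b"), ("b", "c"), ("c", "a")]:
            idx.add_record(DirectedEdgeRecord(t, h, provenance=frozenset({"s"})))
        from dagsynth.graph import CycleError

        with pytest.raises(CycleError):
            synthesise(idx)

    def test_unknown_focal_node_rejected(self):
        idx = index_edges(one_edge_dag(), "s")
        with pytest.raises(GraphError):
            synthesise(idx, focal=("x", "nope"))


class TestReviewerNode:
    def test_new_node_yields_one_pending_pair_per_existing_node(self, bundle):
        idag = bundle.final_idag
        g, pending = add_reviewer_node(idag, NodeRef(id="peer_alc"))
        assert len(pending) == len(idag.nodes)
        assert g.roles_of("peer_alc") == {"reviewer_added"}

    def test_duplicate_id_rejected(self, bundle):
        with pytest.raises(GraphError):
            add_reviewer_node(bundle.final_idag, NodeRef(id="adol_alc"))

    def test_all_delete_verdicts_leave_isolated_node_with_warning(self, bundle):
        from dagsynth.translation import CriteriaAssessment

        idag = bundle.final_idag
        g, pending = add_reviewer_node(idag, NodeRef(id="zzz"))
        assessments = []
        for a, b in pending:
            assessments.append(
                CriteriaAssessment(
                    study_id="rev", tail=a, head=b,
                    criterion="temporality", verdict="no",
                )
            )
            assessments.append(
                CriteriaAssessment(
                    study_id="rev", tail=b, head=a,
                    criterion="temporality", verdict="no",
                )
            )
        log = DecisionLog()
        resolved, _ = resolve_pending(
            g, bundle.final_index, assessments, "rev", log=log, pairs=pending
        )
        assert resolved.edges == idag.edges
        assert "zzz" in resolved.nodes
        warnings = [e for e in log.select(action="isolated_node_warning")]
        assert [e.subject for e in warnings] == ["zzz"]


def two_control_fan():
    """c1 and c2 each point at exactly {x, y}: identical in/out neighbourhoods."""
    g = MixedGraph(stage=Stage.INTEGRATED)
    for nid in ("c1", "c2", "x", "y"):
        g.add_node(nid)
    for c in ("c1", "c2"):
        g.add_edge(c, "x", status=Status.RETAINED)
        g.add_edge(c, "y", status=Status.RETAINED)
    g.add_edge("x", "y", status=Status.RETAINED)
    return g


class TestRecombination:
    def test_identical_io_pair_is_candidate(self):
        cands = recombination_candidates(two_control_fan())
        assert (("c1", "c2"), {"identical_io"}) in cands

    def test_connected_nodes_never_candidates(self):
        g = two_control_fan()
        pairs = {p for p, _ in recombination_candidates(g)}
        assert frozenset({"x", "y"}) not in {frozenset(p) for p in pairs}

    def test_empty_graph_has_no_candidates(self):
        assert recombination_candidates(MixedGraph()) == []

    def test_theory_flagged_pair_reported(self, bundle):
        # parental monitoring and autonomy granting as categories of
        # parenting practice — modelled here on two structurally different controls
        g = two_control_fan()
        g.add_node("c3")
        g.add_edge("c3", "x", status=Status.RETAINED)
        cands = dict(recombination_candidates(g, theory_flags=[("c1", "c3")]))
        assert "theory_flagged" in cands[("c1", "c3")]

    def test_merge_preserves_reachability_among_remaining_nodes(self):
        g = two_control_fan()
        merged = recombine(
            g, ("c1", "c2"), NodeRef(id="parenting"), "categories of one concept"
        )
        assert set(merged.nodes) == {"parenting", "x", "y"}
        before = g.to_networkx()
        after = merged.to_networkx()
        for a in ("x", "y"):
            for b in ("x", "y"):
                if a != b:
                    assert nx.has_path(before, a, b) == nx.has_path(after, a, b)
        assert merged.is_acyclic()
        # alias union keeps the constituent identities recoverable
        assert {"c1", "c2"} <= set(merged.nodes["parenting"].aliases)

    def test_merge_of_adjacent_nodes_rejected(self):
        g = two_control_fan()
        with pytest.raises(GraphError):
            recombine(g, ("x", "y"), NodeRef(id="xy"), "nope", force=True)

    def test_non_candidate_requires_force(self):
        g = two_control_fan()
        g.add_node("c3")
        g.add_edge("c3", "x", status=Status.RETAINED)
        with pytest.raises(GraphError):
            recombine(g, ("c1", "c3"), NodeRef(id="m"), "no support")
        merged = recombine(g, ("c1", "c3"), NodeRef(id="m"), "reviewer override", force=True)
        assert "m" in merged.nodes

    def test_merged_parallel_edges_take_worst_confidence(self):
        g = two_control_fan()
        pair = frozenset({"c1", "x"})
        from dataclasses import replace

        g.edges[pair] = replace(g.edges[pair], confidence=Confidence.LOW)
        merged = recombine(g, ("c1", "c2"), NodeRef(id="p"), "merge")
        assert merged.edge("p", "x").confidence is Confidence.LOW

    def test_merge_logged_with_justification(self):
        g = two_control_fan()
        log = DecisionLog()
        recombine(g, ("c1", "c2"), NodeRef(id="p"), "one construct", log=log)
        entry = next(log.select(stage="recombination"))
        assert entry.rationale == "one construct"
        assert entry.verdicts["merged"] == "p"
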