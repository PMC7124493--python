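"""Integration: the directed edge index, I-DAG synthesis and node recombination.

Every retained directed edge from every translated study DAG enters a
provenance-bearing *directed edge index*.  Synthesis pours the index into a
blank graph — edge by edge, in any order, with the same result — producing the
integrated DAG (I-DAG).  Because each new node makes new relationships
possible, synthesis also reports *pending* pairs: node pairs that have been
neither retained nor assessed-and-deleted, which must be routed back through
translation in the context of the I-DAG.  Recombination merges conceptually
equivalent nodes (theory support, or identical in/out neighbourhoods) to keep
a growing I-DAG tractable.

Deletions are first-class index entries.  The pending-pair computation needs
to distinguish "assessed and rejected" from "never assessed", so every
deleted pair is registered with its provenance; this is what makes the
saturation accounting exact: pending + indexed + deleted = all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .graph import (
    Confidence,
    CycleError,
    GraphError,
    MixedGraph,
    NodeRef,
    Orientation,
    Stage,
    Status,
    UnknownNodeError,
)
from .log import DecisionLog, pair_subject
from .translation import CriteriaAssessment, translate_graph

__all__ = [
    "DirectedEdgeRecord",
    "EdgeIndex",
    "index_edges",
    "synthesise",
    "resolve_pending",
    "add_reviewer_node",
    "recombination_candidates",
    "recombine",
]


@dataclass(frozen=True)
class DirectedEdgeRecord:
    """An indexed retained edge with provenance across studies."""

    tail: str
    head: str
    bidirectional: bool = False
    confidence: Confidence = Confidence.NORMAL
    provenance: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self):
        if self.tail == self.head:
            raise GraphError("self-loop record")
        if not self.provenance:
            raise GraphError(f"record {self.tail}->{self.head} has empty provenance")
        object.__setattr__(self, "confidence", Confidence(self.confidence))
        object.__setattr__(self, "provenance", frozenset(self.provenance))

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.tail, self.head))


@dataclass
class EdgeIndex:
    """Registry of retained edges, recorded deletions and direction conflicts."""

    records: dict[frozenset, DirectedEdgeRecord] = field(default_factory=dict)
    deletions: dict[frozenset, frozenset] = field(default_factory=dict)  # pair -> study ids
    conflicts: dict[frozenset, list] = field(default_factory=dict)  # pair -> rival records

    def add_record(self, record: DirectedEdgeRecord) -> None:
        """Insert or merge; opposite directions flag a conflict, never auto-merge.

        Bidirectionality is a substantive reviewer claim, so two studies
        disagreeing on direction are queued for re-assessment instead of
        silently becoming a bidirectional edge.
        """
        if record.pair in self.deletions:
            raise GraphError(
                f"pair {sorted(record.pair)} already registered as deleted"
            )
        existing = self.records.get(record.pair)
        if existing is None:
            self.records[record.pair] = record
            return
        same_direction = (existing.tail, existing.head) == (record.tail, record.head)
        if same_direction and existing.bidirectional == record.bidirectional:
            worst = (
                Confidence.LOW
                if Confidence.LOW in (existing.confidence, record.confidence)
                else Confidence.NORMAL
            )
            notes = existing.notes
            if record.notes and record.notes not in notes:
                notes = f"{notes}; {record.notes}" if notes else record.notes
            self.records[record.pair] = replace(
                existing,
                confidence=worst,
                provenance=existing.provenance | record.provenance,
                notes=notes,
            )
        else:
            self.conflicts.setdefault(record.pair, []).append(record)

    def register_deletion(self, pair, study_id: str) -> None:
        pair = frozenset(pair)
        if pair in self.records:
            raise GraphError(f"pair {sorted(pair)} already carries a retained record")
        self.deletions[pair] = self.deletions.get(pair, frozenset()) | {study_id}

    def merge(self, other: "EdgeIndex") -> "EdgeIndex":
        """Commutative, associative, idempotent union of two indices."""
        out = EdgeIndex(
            records=dict(self.records),
            deletions=dict(self.deletions),
            conflicts={k: list(v) for k, v in self.conflicts.items()},
        )
        for rec in other.records.values():
            out.add_record(rec)
        for pair, studies in other.deletions.items():
            for sid in sorted(studies):
                out.register_deletion(pair, sid)
        for pair, rivals in other.conflicts.items():
            known = out.conflicts.setdefault(pair, [])
            known.extend(r for r in rivals if r not in known)
        return out

    def node_ids(self) -> set[str]:
        ids: set[str] = set()
        for rec in self.records.values():
            ids.update(rec.pair)
        return ids


def index_edges(
    dag: MixedGraph,
    study_id: str,
    index: EdgeIndex | None = None,
    deleted_pairs=(),
    log: DecisionLog | None = None,
) -> EdgeIndex:
    """Enter every retained edge of a translated DAG into the index.

    Re-indexing an already-known pair merges provenance (idempotent).
    ``deleted_pairs`` registers the pairs the study assessed and rejected so
    they do not resurface as pending during synthesis.
    """
    if dag.stage not in (Stage.TRANSLATED, Stage.INTEGRATED):
        raise GraphError(f"cannot index a graph at stage {dag.stage.value}")
    dag.validate()
    index = index if index is not None else EdgeIndex()
    for e in sorted(dag.edges.values(), key=lambda e: (e.tail, e.head)):
        if e.status is not Status.RETAINED:
            continue
        record = DirectedEdgeRecord(
            tail=e.tail,
            head=e.head,
            bidirectional=e.orientation is Orientation.BIDIRECTIONAL,
            confidence=e.confidence,
            provenance=frozenset({study_id}),
        )
        index.add_record(record)
        if log is not None:
            log.append(
                "synthesis",
                pair_subject(e.tail, e.head),
                "indexed",
                verdicts={"edge": f"{e.tail}->{e.head}", "study": study_id},
            )
    for pair in deleted_pairs:
        index.register_deletion(frozenset(pair), study_id)
        if log is not None:
            log.append(
                "synthesis",
                pair_subject(*sorted(pair)),
                "deletion_registered",
                verdicts={"study": study_id},
            )
    return index


def synthesise(
    index: EdgeIndex,
    focal: tuple[str, str] | None = None,
    log: DecisionLog | None = None,
) -> tuple[MixedGraph, list[tuple[str, str]]]:
    """Pour the edge index into a blank graph, yielding the I-DAG.

    The I-DAG is exactly the union of indexed edges and their nodes, so the
    insertion order is immaterial.  Returns the graph plus the sorted pending
    pairs — unordered node pairs with neither a record nor a registered
    deletion — which must be assessed through translation in the I-DAG
    context.  A cyclic union or an unresolved direction conflict is an error.
    """
    if not index.records:
        raise GraphError("cannot synthesise an empty edge index")
    if index.conflicts:
        pairs = sorted(sorted(p) for p in index.conflicts)
        raise GraphError(
            f"index holds unresolved direction conflicts on pairs {pairs}; "
            "re-assess before synthesis"
        )
    g = MixedGraph(stage=Stage.INTEGRATED)
    for nid in sorted(index.node_ids()):
        g.add_node(nid)
    if focal is not None:
        x, y = focal
        for nid in (x, y):
            if nid not in g.nodes:
                raise UnknownNodeError(nid)
        g.add_node(x, roles={"exposure"})
        g.add_node(y, roles={"outcome"})
    for rec in index.records.values():
        orientation = (
            Orientation.BIDIRECTIONAL if rec.bidirectional else Orientation.DIRECTED
        )
        g.add_edge(
            rec.tail, rec.head, orientation, Status.RETAINED, rec.confidence,
            frozenset((sid, "synthesis") for sid in rec.provenance),
        )
        if log is not None:
            log.append(
                "synthesis",
                pair_subject(rec.tail, rec.head),
                "synthesised",
                verdicts={"edge": f"{rec.tail}->{rec.head}"},
            )
    if not g.is_acyclic():
        raise CycleError(g.find_cycles())
    pending = pending_pairs(g, index)
    return g, pending


def pending_pairs(g: MixedGraph, index: EdgeIndex) -> list[tuple[str, str]]:
    """All unordered node pairs neither indexed nor registered as deleted."""
    ids = sorted(g.nodes)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pair = frozenset((a, b))
            if pair not in index.records and pair not in index.deletions:
                out.append((a, b))
    return out


def resolve_pending(
    idag: MixedGraph,
    index: EdgeIndex,
    assessments: list[CriteriaAssessment],
    provenance_id: str,
    log: DecisionLog | None = None,
    pairs=None,
) -> tuple[MixedGraph, EdgeIndex]:
    """Route pending pairs back through translation in the I-DAG context.

    Adds an unassigned candidate edge for each pending pair (or the subset
    ``pairs``), resolves them with the supplied assessments, and records the
    outcomes in the index under ``provenance_id``.
    """
    todo = pairs if pairs is not None else pending_pairs(idag, index)
    g = idag.copy()
    for a, b in todo:
        if g.edge(a, b) is None:
            g.add_edge(a, b, Orientation.UNASSIGNED, Status.CANDIDATE)
    translated, log = translate_graph(g, assessments, log=log)
    new_index = index.merge(EdgeIndex())
    for a, b in todo:
        e = translated.edge(a, b)
        if e is None:
            new_index.register_deletion(frozenset((a, b)), provenance_id)
        else:
            new_index.add_record(
                DirectedEdgeRecord(
                    tail=e.tail,
                    head=e.head,
                    bidirectional=e.orientation is Orientation.BIDIRECTIONAL,
                    confidence=e.confidence,
                    provenance=frozenset({provenance_id}),
                )
            )
    isolated = [
        nid
        for nid in translated.nodes
        if not any(nid in e.pair for e in translated.edges.values())
    ]
    if isolated and log is not None:
        for nid in sorted(isolated):
            log.append(
                "synthesis",
                nid,
                "isolated_node_warning",
                rationale=(
                    "node influences fewer than two others after assessment; "
                    "inclusion rule not met"
                ),
            )
    return translated, new_index


def add_reviewer_node(
    idag: MixedGraph, node: NodeRef, log: DecisionLog | None = None
) -> tuple[MixedGraph, list[tuple[str, str]]]:
    """Add a reviewer-supplied variable missing from the literature.

    Returns the pending pairs linking it to every existing node: these are
    mapped and translated in the context of the I-DAG, not a fresh implied
    graph.
    """
    if node.id in idag.nodes:
        raise GraphError(f"node id collision: {node.id!r}")
    g = idag.copy()
    existing = sorted(g.nodes)
    g.add_node(node, roles={"reviewer_added"})
    pending = [tuple(sorted((node.id, other))) for other in existing]
    if log is not None:
        log.append(
            "synthesis",
            node.id,
            "reviewer_node_added",
            verdicts={"pending_pairs": len(pending)},
        )
    return g, sorted(pending)


def _neighbourhoods(g: MixedGraph, nid: str, exclude: str):
    ins, outs = set(), set()
    for e in g.edges.values():
        if e.status is not Status.RETAINED:
            continue
        if e.orientation is Orientation.DIRECTED:
            if e.head == nid and e.tail != exclude:
                ins.add(e.tail)
            if e.tail == nid and e.head != exclude:
                outs.add(e.head)
        elif e.orientation is Orientation.BIDIRECTIONAL and nid in e.pair:
            other = (e.pair - {nid}).pop()
            if other != exclude:
                ins.add(other)
                outs.add(other)
    return ins, outs


def recombination_candidates(
    idag: MixedGraph, theory_flags=()
) -> list[tuple[tuple[str, str], set[str]]]:
    """Node pairs that are plausible merges, with the supporting indication.

    ``identical_io``: in-neighbour and out-neighbour sets (each excluding the
    other member) coincide — the structural indication.  ``theory_flagged``:
    the reviewer asserts the nodes are categories of one concept.  Pairs
    joined by an edge are never candidates (merging cause with effect would
    create a self-loop).
    """
    flagged = {frozenset(p) for p in theory_flags}
    ids = sorted(idag.nodes)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pair = frozenset((a, b))
            if idag.edges.get(pair) is not None:
                continue
            evidence: set[str] = set()
            if pair in flagged:
                evidence.add("theory_flagged")
            a_in, a_out = _neighbourhoods(idag, a, b)
            b_in, b_out = _neighbourhoods(idag, b, a)
            if a_in == b_in and a_out == b_out:
                evidence.add("identical_io")
            if evidence:
                out.append(((a, b), evidence))
    return out


def recombine(
    idag: MixedGraph,
    pair: tuple[str, str],
    merged: NodeRef,
    justification: str,
    log: DecisionLog | None = None,
    force: bool = False,
    theory_flags=(),
) -> MixedGraph:
    """Merge two nodes into one; edges, provenance, aliases and roles union.

    Requires the pair to be a current recombination candidate unless
    ``force`` is set (with the justification logged either way).  Parallel
    merged edges take worst-case confidence.  Refuses merges that would
    create a self-loop (adjacent pair), contradictory directions or a cycle.
    """
    a, b = pair
    for nid in (a, b):
        if nid not in idag.nodes:
            raise UnknownNodeError(nid)
    if merged.id in idag.nodes and merged.id not in (a, b):
        raise GraphError(f"merged node id collision: {merged.id!r}")
    if idag.edge(a, b) is not None:
        raise GraphError(f"cannot recombine adjacent nodes {a!r} and {b!r}")
    if not force:
        candidates = {frozenset(p) for p, _ in recombination_candidates(idag, theory_flags)}
        if frozenset(pair) not in candidates:
            raise GraphError(
                f"{{{a}, {b}}} is not a recombination candidate "
                "(no theory flag, neighbourhoods differ); pass force=True to override"
            )

    old_a, old_b = idag.nodes[a], idag.nodes[b]
    merged = NodeRef(
        id=merged.id,
        label=merged.label,
        aliases=frozenset(merged.aliases) | old_a.aliases | old_b.aliases | {a, b},
        measured=merged.measured,
    )
    g = MixedGraph(stage=idag.stage)
    for nid, node in idag.nodes.items():
        if nid in (a, b):
            continue
        g.add_node(node, roles=idag.roles.get(nid))
    g.add_node(merged, roles=(idag.roles.get(a, set()) | idag.roles.get(b, set())) or None)

    for e in sorted(idag.edges.values(), key=lambda e: (e.tail, e.head)):
        tail = merged.id if e.tail in (a, b) else e.tail
        head = merged.id if e.head in (a, b) else e.head
        existing = g.edge(tail, head)
        if existing is None:
            g.add_edge(tail, head, e.orientation, e.status, e.confidence, e.provenance)
            continue
        if (
            existing.orientation is not e.orientation
            or (
                e.orientation is Orientation.DIRECTED
                and (existing.tail, existing.head) != (tail, head)
            )
        ):
            raise CycleError([(tail, head)])
        worst = (
            Confidence.LOW
            if Confidence.LOW in (existing.confidence, e.confidence)
            else Confidence.NORMAL
        )
        g.edges[existing.pair] = replace(
            existing,
            confidence=worst,
            provenance=existing.provenance | e.provenance,
        )
    if not g.is_acyclic():
        raise CycleError(g.find_cycles())
    if log is not None:
        log.append(
            "recombination",
            pair_subject(a, b),
            "recombined",
            verdicts={"merged": merged.id},
            rationale=justification,
        )
    return g
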