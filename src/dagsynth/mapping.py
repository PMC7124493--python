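"""Mapping: turn one reviewed study's conclusions into its saturated implied graph.

The implied graph (IG) is a transparent structural template for the study as
published, accurate or otherwise.  The outcome and exposure become DAG nodes
joined exposure->outcome; every control variable enters as a mutual cause of
exposure and outcome (a confounder is the simplest structure that opens a
backdoor path, which is what controlling presumes); mediators and instruments
are drawn as the study concluded; finally the graph is saturated so that every
remaining pair — notably control–control pairs — carries an unassigned edge
awaiting translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import Confidence, GraphError, MixedGraph, NodeRef, Orientation, Stage, Status

__all__ = ["StudyRecord", "map_study", "roles_of"]


@dataclass
class StudyRecord:
    """One reviewed study's exposure/outcome/control/mediator structure.

    ``mediators`` are (tail, head) edges as concluded by the study (a mediator
    M of X on Y contributes (X, M) and (M, Y)); ``instruments`` are
    (instrument, target exposure) pairs.
    """

    study_id: str
    exposures: list[str]
    outcomes: list[str]
    controls: list[str] = field(default_factory=list)
    mediators: list[tuple[str, str]] = field(default_factory=list)
    instruments: list[tuple[str, str]] = field(default_factory=list)
    citation: str = ""
    labels: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.mediators = [tuple(m) for m in self.mediators]
        self.instruments = [tuple(i) for i in self.instruments]
        self.validate()

    def validate(self) -> None:
        if not self.study_id:
            raise GraphError("study_id required")
        if not self.exposures or not self.outcomes:
            raise GraphError(f"{self.study_id}: exposures and outcomes must be non-empty")
        exp, out, ctl = set(self.exposures), set(self.outcomes), set(self.controls)
        if exp & out:
            raise GraphError(f"{self.study_id}: exposures and outcomes overlap: {sorted(exp & out)}")
        if ctl & (exp | out):
            raise GraphError(
                f"{self.study_id}: controls overlap exposures/outcomes: {sorted(ctl & (exp | out))}"
            )
        for tail, head in self.mediators:
            if tail == head:
                raise GraphError(f"{self.study_id}: mediator self-loop {tail!r}")
        for inst, target in self.instruments:
            if target not in exp:
                raise GraphError(
                    f"{self.study_id}: instrument {inst!r} targets non-exposure {target!r}"
                )

    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for nid in (
            list(self.exposures)
            + list(self.outcomes)
            + list(self.controls)
            + [n for m in self.mediators for n in m]
            + [i for i, _ in self.instruments]
        ):
            seen.setdefault(nid)
        return list(seen)


def map_study(record: StudyRecord) -> MixedGraph:
    """Build the study's saturated implied graph (stage=implied).

    Directed candidate edges: exposure->outcome for every focal pair;
    control->exposure and control->outcome for every control; mediator and
    instrument->exposure edges as listed.  Saturation then fills every
    remaining pair with an unassigned candidate edge.  For a study with one
    exposure, one outcome, k controls and no mediators/instruments this gives
    1 + 2k directed candidates.
    """
    record.validate()
    g = MixedGraph(stage=Stage.IMPLIED)
    for nid in record.node_ids():
        g.add_node(
            NodeRef(
                id=nid,
                label=record.labels.get(nid, ""),
                aliases=frozenset(record.aliases.get(nid, ())),
            )
        )
    for x in record.exposures:
        g.add_node(x, roles={"exposure"})
    for y in record.outcomes:
        g.add_node(y, roles={"outcome"})
    for c in record.controls:
        g.add_node(c, roles={"control"})
    for tail, _ in record.mediators:
        if tail not in set(record.exposures) | set(record.outcomes) | set(record.controls):
            g.add_node(tail, roles={"mediator"})
    for _, head in record.mediators:
        if head not in set(record.exposures) | set(record.outcomes) | set(record.controls):
            g.add_node(head, roles={"mediator"})
    for inst, _ in record.instruments:
        g.add_node(inst, roles={"instrument"})

    prov = frozenset({(record.study_id, "mapping")})

    def draw(tail: str, head: str) -> None:
        existing = g.edge(tail, head)
        if existing is not None and existing.orientation is Orientation.DIRECTED:
            if (existing.tail, existing.head) != (tail, head):
                raise GraphError(
                    f"{record.study_id}: study structure posits both {tail}->{head} "
                    f"and {existing.tail}->{existing.head}"
                )
            return
        g.add_edge(tail, head, Orientation.DIRECTED, Status.CANDIDATE,
                   Confidence.NORMAL, prov)

    for x in record.exposures:
        for y in record.outcomes:
            draw(x, y)
    for c in record.controls:
        for x in record.exposures:
            draw(c, x)
        for y in record.outcomes:
            draw(c, y)
    for tail, head in record.mediators:
        draw(tail, head)
    for inst, target in record.instruments:
        draw(inst, target)

    return g.saturate()


def roles_of(graph: MixedGraph, node_id: str) -> set[str]:
    """Recorded workflow roles of a node (exposure/outcome/control/...)."""
    return graph.roles_of(node_id)
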