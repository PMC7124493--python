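"""Mixed-graph container shared by every stage of the DAG-building workflow.

A :class:`MixedGraph` holds nodes plus edges whose orientation may be
*directed*, *unassigned* (drawn during saturation, direction not yet decided)
or *bidirectional* (both directions survived assessment).  The same container
represents a study's saturated implied graph, its translated DAG, and the
integrated DAG synthesised across studies; a ``stage`` flag records which.

Acyclicity is definitional for a causal DAG, but only the *directed, retained*
edges participate in the cycle check: an unassigned edge makes no directional
claim yet, and a bidirectional edge stands for a latent common cause (see
:mod:`dagsynth.analysis`), not a 2-cycle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "Orientation",
    "Status",
    "Confidence",
    "Stage",
    "NodeRef",
    "Edge",
    "MixedGraph",
    "GraphError",
    "UnknownNodeError",
    "PairOccupiedError",
    "CycleError",
]


class GraphError(ValueError):
    """Base class for graph-invariant violations."""


class UnknownNodeError(GraphError, KeyError):
    def __init__(self, node_id: str):
        super().__init__(f"unknown node id: {node_id!r}")
        self.node_id = node_id


class PairOccupiedError(GraphError):
    def __init__(self, pair):
        a, b = sorted(pair)
        super().__init__(f"node pair {{{a}, {b}}} already carries a retained edge")
        self.pair = frozenset(pair)


class CycleError(GraphError):
    """Raised when a resolution set induces a directed cycle.

    The offending cycles are reported, never silently repaired: deleting a
    reviewer-retained edge is a substantive decision the tool must not make.
    """

    def __init__(self, cycles):
        self.cycles = [tuple(c) for c in cycles]
        shown = "; ".join(" -> ".join(c + (c[0],)) for c in self.cycles[:5])
        super().__init__(f"directed edges form {len(self.cycles)} cycle(s): {shown}")


class Orientation(str, enum.Enum):
    DIRECTED = "directed"
    UNASSIGNED = "unassigned"
    BIDIRECTIONAL = "bidirectional"


class Status(str, enum.Enum):
    CANDIDATE = "candidate"
    RETAINED = "retained"
    DELETED = "deleted"


class Confidence(str, enum.Enum):
    NORMAL = "normal"
    LOW = "low"


class Stage(str, enum.Enum):
    IMPLIED = "implied"
    TRANSLATED = "translated"
    INTEGRATED = "integrated"


#: Node roles recognised across the workflow.
ROLES = frozenset(
    {"exposure", "outcome", "control", "mediator", "instrument", "reviewer_added"}
)


@dataclass(frozen=True)
class NodeRef:
    """A graph node: a variable, measured or unmeasured.

    ``id`` is the canonical token (lowercase, no whitespace); ``aliases`` map
    study-specific variable names onto it.  Concept merging is an explicit,
    logged recombination step — never fuzzy string matching — so alias sets of
    distinct nodes must stay disjoint.
    """

    id: str
    label: str = ""
    aliases: frozenset[str] = frozenset()
    measured: bool = True

    def __post_init__(self):
        if not self.id or self.id != self.id.lower() or any(c.isspace() for c in self.id):
            raise GraphError(f"node id must be a lowercase whitespace-free token: {self.id!r}")
        if not self.label:
            object.__setattr__(self, "label", self.id.replace("_", " "))
        object.__setattr__(self, "aliases", frozenset(self.aliases))


@dataclass(frozen=True)
class Edge:
    """One edge on an unordered node pair.

    The pair is the unit of assessment: "posited" and "reverse" are states of
    a single edge, so at most one edge may occupy a pair.  ``tail``/``head``
    order is meaningful only when ``orientation`` is directed.
    """

    tail: str
    head: str
    orientation: Orientation = Orientation.DIRECTED
    status: Status = Status.CANDIDATE
    confidence: Confidence = Confidence.NORMAL
    provenance: frozenset[tuple[str, str]] = frozenset()  # (study id, stage) pairs

    def __post_init__(self):
        if self.tail == self.head:
            raise GraphError(f"self-loop forbidden: {self.tail!r}")
        if self.orientation is Orientation.UNASSIGNED and self.status is not Status.CANDIDATE:
            raise GraphError("unassigned orientation is only legal while status=candidate")
        object.__setattr__(self, "provenance", frozenset(self.provenance))

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.tail, self.head))


@dataclass
class MixedGraph:
    """Nodes, pair-unique edges, per-node roles and a workflow stage flag."""

    nodes: dict[str, NodeRef] = field(default_factory=dict)
    edges: dict[frozenset[str], Edge] = field(default_factory=dict)
    roles: dict[str, set[str]] = field(default_factory=dict)
    stage: Stage = Stage.IMPLIED

    # -- construction -----------------------------------------------------

    def add_node(self, node: NodeRef | str, roles: set[str] | None = None) -> NodeRef:
        if isinstance(node, str):
            node = self.nodes.get(node, NodeRef(id=node))
        if node.id in self.nodes:
            existing = self.nodes[node.id]
            if existing != node:
                raise GraphError(f"node id collision: {node.id!r}")
        else:
            taken = set().union(*(n.aliases for n in self.nodes.values())) if self.nodes else set()
            if node.aliases & taken:
                raise GraphError(
                    f"alias collision for node {node.id!r}: {sorted(node.aliases & taken)}"
                )
            self.nodes[node.id] = node
        if roles:
            bad = set(roles) - ROLES
            if bad:
                raise GraphError(f"unknown roles: {sorted(bad)}")
            self.roles.setdefault(node.id, set()).update(roles)
        return self.nodes[node.id]

    def add_edge(
        self,
        tail: str,
        head: str,
        orientation: Orientation | str = Orientation.DIRECTED,
        status: Status | str = Status.CANDIDATE,
        confidence: Confidence | str = Confidence.NORMAL,
        provenance=frozenset(),
    ) -> Edge:
        """Insert an edge on the unordered pair ``{tail, head}``.

        A pair already occupied by a candidate edge is replaced (translation
        overwrites saturation placeholders); a pair occupied by a retained
        edge is an error.
        """
        for nid in (tail, head):
            if nid not in self.nodes:
                raise UnknownNodeError(nid)
        edge = Edge(
            tail,
            head,
            Orientation(orientation),
            Status(status),
            Confidence(confidence),
            provenance,
        )
        old = self.edges.get(edge.pair)
        if old is not None and old.status is not Status.CANDIDATE:
            raise PairOccupiedError(edge.pair)
        self.edges[edge.pair] = edge
        return edge

    def remove_edge(self, tail: str, head: str) -> None:
        pair = frozenset((tail, head))
        if pair not in self.edges:
            raise GraphError(f"no edge on pair {sorted(pair)}")
        del self.edges[pair]

    # -- queries ----------------------------------------------------------

    def edge(self, a: str, b: str) -> Edge | None:
        return self.edges.get(frozenset((a, b)))

    def roles_of(self, node_id: str) -> set[str]:
        if node_id not in self.nodes:
            raise UnknownNodeError(node_id)
        return set(self.roles.get(node_id, set()))

    def directed_edges(self, status: Status | None = Status.RETAINED):
        """Directed edges, optionally filtered by status (None = any)."""
        return [
            e
            for e in self.edges.values()
            if e.orientation is Orientation.DIRECTED
            and (status is None or e.status is status)
        ]

    def bidirectional_edges(self):
        return [e for e in self.edges.values() if e.orientation is Orientation.BIDIRECTIONAL]

    def candidate_edges(self):
        return [e for e in self.edges.values() if e.status is Status.CANDIDATE]

    def to_networkx(self, status: Status | None = Status.RETAINED) -> nx.DiGraph:
        """The directed subgraph as a networkx DiGraph (nodes always included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.tail, e.head) for e in self.directed_edges(status))
        return g

    def is_acyclic(self) -> bool:
        """True iff the retained, directed subgraph has no directed cycle."""
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def find_cycles(self) -> list[tuple[str, ...]]:
        return [tuple(c) for c in nx.simple_cycles(self.to_networkx())]

    def validate(self) -> None:
        """Check the container invariants; raise :class:`GraphError` on breach."""
        for pair, e in self.edges.items():
            if e.pair != pair:
                raise GraphError(f"edge stored under wrong pair: {sorted(pair)}")
            for nid in pair:
                if nid not in self.nodes:
                    raise UnknownNodeError(nid)
        if self.stage in (Stage.TRANSLATED, Stage.INTEGRATED):
            if self.candidate_edges():
                raise GraphError(f"{self.stage.value} graph still has candidate edges")
            if not self.is_acyclic():
                raise CycleError(self.find_cycles())

    # -- whole-graph operations -------------------------------------------

    def copy(self) -> "MixedGraph":
        return MixedGraph(
            nodes=dict(self.nodes),
            edges=dict(self.edges),
            roles={k: set(v) for k, v in self.roles.items()},
            stage=self.stage,
        )

    def saturate(self) -> "MixedGraph":
        """Return a copy in which every unordered node pair carries an edge.

        Omitting an edge asserts *no effect* — the stronger claim — so the
        workflow works backwards from saturation.  Missing pairs are filled
        with unassigned candidate edges; existing edges are untouched.
        Idempotent; yields exactly n(n-1)/2 edges on n nodes.
        """
        g = self.copy()
        ids = sorted(g.nodes)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if frozenset((a, b)) not in g.edges:
                    g.add_edge(a, b, Orientation.UNASSIGNED, Status.CANDIDATE)
        return g

    def edge_signature(self):
        """Canonical labelled edge set, for graph equality irrespective of build order."""
        sig = set()
        for e in self.edges.values():
            if e.orientation is Orientation.DIRECTED:
                sig.add((e.tail, e.head, "directed", e.status.value))
            else:
                a, b = sorted(e.pair)
                sig.add((a, b, e.orientation.value, e.status.value))
        return frozenset(sig)

    def equivalent(self, other: "MixedGraph") -> bool:
        return (
            set(self.nodes) == set(other.nodes)
            and self.edge_signature() == other.edge_signature()
        )


def relabelled(edge: Edge, tail: str, head: str) -> Edge:
    """A copy of ``edge`` with endpoints replaced (used by recombination)."""
    return replace(edge, tail=tail, head=head)
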