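"""Backdoor analysis of a translated or integrated DAG.

The point of building the DAG is to direct adjustment strategy: which
covariates close backdoor paths (confounders), which lie on the causal
pathway (mediators, adjusting for them over-controls the effect), and which
open spurious paths when conditioned on (colliders and their descendants).

Bidirectional edges — both directions retained during translation — are read
as a latent common cause: u <-> v becomes u <- L_uv -> v with L_uv unmeasured
and never eligible for adjustment.  After that expansion everything here runs
on an ordinary DAG: d-separation, backdoor-path enumeration, exhaustive
minimal-adjustment-set search (fine at the scale of reviewed-literature
graphs), covariate-role classification and what-if reports for a proposed
conditioning set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .graph import GraphError, MixedGraph, Orientation, Status, UnknownNodeError

__all__ = [
    "AnalysisGraph",
    "PathReport",
    "AdjustmentReport",
    "d_separated",
    "backdoor_paths",
    "minimal_adjustment_sets",
    "classify_covariate",
    "adjustment_consequences",
]

#: Exhaustive subset search is exponential; beyond this many measured nodes a
#: branch-and-bound strategy would be needed, which this toolkit does not ship.
MAX_ADJUSTMENT_NODES = 20


@dataclass
class AnalysisGraph:
    """A pure DAG view: directed edges only, latent nodes marked unmeasured."""

    digraph: nx.DiGraph
    measured: dict[str, bool] = field(default_factory=dict)
    latent: set[str] = field(default_factory=set)

    @classmethod
    def from_mixed(cls, g: MixedGraph) -> "AnalysisGraph":
        dg = nx.DiGraph()
        measured = {}
        latent: set[str] = set()
        for nid, node in g.nodes.items():
            dg.add_node(nid)
            measured[nid] = node.measured
        for e in g.edges.values():
            if e.status is not Status.RETAINED:
                continue
            if e.orientation is Orientation.DIRECTED:
                dg.add_edge(e.tail, e.head)
            elif e.orientation is Orientation.BIDIRECTIONAL:
                a, b = sorted(e.pair)
                lid = f"l_{a}_{b}"
                dg.add_edge(lid, a)
                dg.add_edge(lid, b)
                measured[lid] = False
                latent.add(lid)
            else:
                raise GraphError("unassigned edge in analysis input; translate first")
        if not nx.is_directed_acyclic_graph(dg):
            raise GraphError("analysis graph must be acyclic")
        return cls(digraph=dg, measured=measured, latent=latent)

    @classmethod
    def from_edges(cls, edges, nodes=(), unmeasured=()) -> "AnalysisGraph":
        dg = nx.DiGraph()
        dg.add_nodes_from(nodes)
        dg.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(dg):
            raise GraphError("analysis graph must be acyclic")
        unmeasured = set(unmeasured)
        return cls(
            digraph=dg,
            measured={n: n not in unmeasured for n in dg.nodes},
            latent=set(),
        )

    def check(self, *node_ids):
        for nid in node_ids:
            if nid not in self.digraph:
                raise UnknownNodeError(nid)

    def measured_nodes(self) -> set[str]:
        return {n for n, m in self.measured.items() if m}


@dataclass(frozen=True)
class PathReport:
    """One x–y path with per-step arrow directions.

    ``arrows[i]`` is "->" when the edge runs nodes[i] -> nodes[i+1], else
    "<-".  A path is causal when every arrow points forward; it is a backdoor
    path when the first arrow points into x.
    """

    nodes: tuple[str, ...]
    arrows: tuple[str, ...]
    kind: str  # causal | backdoor | other
    open_given_empty: bool = True

    def __str__(self) -> str:
        parts = [self.nodes[0]]
        for arrow, node in zip(self.arrows, self.nodes[1:]):
            parts.append(arrow)
            parts.append(node)
        return " ".join(parts)

    def colliders(self) -> tuple[str, ...]:
        out = []
        for i in range(1, len(self.nodes) - 1):
            if self.arrows[i - 1] == "->" and self.arrows[i] == "<-":
                out.append(self.nodes[i])
        return tuple(out)

    def is_open(self, g: AnalysisGraph, Z) -> bool:
        """Standard per-path blocking: chains/forks blocked iff the middle
        node is conditioned on; colliders open iff the collider or one of its
        descendants is conditioned on."""
        Z = set(Z)
        colliders = set(self.colliders())
        for i in range(1, len(self.nodes) - 1):
            m = self.nodes[i]
            if m in colliders:
                desc = nx.descendants(g.digraph, m) | {m}
                if not (desc & Z):
                    return False
            elif m in Z:
                return False
        return True


def _enumerate_paths(g: AnalysisGraph, x: str, y: str) -> list[PathReport]:
    """All acyclic paths between x and y in the undirected sense."""
    und = g.digraph.to_undirected(as_view=False)
    reports = []
    for nodes in nx.all_simple_paths(und, x, y):
        arrows = tuple(
            "->" if g.digraph.has_edge(u, v) else "<-"
            for u, v in zip(nodes, nodes[1:])
        )
        if all(a == "->" for a in arrows):
            kind = "causal"
        elif arrows[0] == "<-":
            kind = "backdoor"
        else:
            kind = "other"
        report = PathReport(tuple(nodes), arrows, kind)
        report = PathReport(
            report.nodes, report.arrows, report.kind, report.is_open(g, set())
        )
        reports.append(report)
    return reports


def d_separated(g: AnalysisGraph, x: str, y: str, Z) -> bool:
    """True iff every x–y path is blocked given Z."""
    Z = set(Z)
    g.check(x, y, *Z)
    if x in Z or y in Z:
        raise GraphError("x and y must not be in the conditioning set")
    return nx.is_d_separator(g.digraph, {x}, {y}, Z)


def backdoor_paths(g: AnalysisGraph, x: str, y: str) -> list[PathReport]:
    """All paths x..y whose first edge points into x, with open/blocked status
    given the empty conditioning set."""
    g.check(x, y)
    if x == y:
        raise GraphError("exposure and outcome must differ")
    return [p for p in _enumerate_paths(g, x, y) if p.kind == "backdoor"]


def _satisfies_backdoor(g: AnalysisGraph, x: str, y: str, Z: set, forbidden: set) -> bool:
    if Z & forbidden:
        return False
    stripped = g.digraph.copy()
    stripped.remove_edges_from(list(stripped.out_edges(x)))
    return nx.is_d_separator(stripped, {x}, {y}, Z)


def minimal_adjustment_sets(g: AnalysisGraph, x: str, y: str) -> set[frozenset]:
    """All inclusion-minimal measured sets satisfying the backdoor criterion.

    A valid set contains no descendant of x and d-separates x from y in the
    graph with x's outgoing edges removed.  The search enumerates subsets of
    the measured non-descendant nodes by increasing size, pruning supersets
    of accepted sets; latent expansion nodes are never eligible.
    """
    g.check(x, y)
    if x == y:
        raise GraphError("exposure and outcome must differ")
    forbidden = nx.descendants(g.digraph, x) | {x, y}
    candidates = sorted(g.measured_nodes() - forbidden)
    if len(candidates) > MAX_ADJUSTMENT_NODES:
        raise GraphError(
            f"{len(candidates)} measurable candidates exceed the exhaustive-search "
            f"cap of {MAX_ADJUSTMENT_NODES}; prune the graph or extend the search"
        )
    minimal: list[frozenset] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            Z = frozenset(combo)
            if any(m <= Z for m in minimal):
                continue
            if _satisfies_backdoor(g, x, y, set(Z), nx.descendants(g.digraph, x)):
                minimal.append(Z)
    return set(minimal)


ROLE_ORDER = (
    "mediator",
    "confounder",
    "collider_on_path",
    "risk_factor_only",
    "instrument_like",
)


def classify_covariate(g: AnalysisGraph, x: str, y: str, v: str) -> tuple[str, ...]:
    """Roles of covariate v relative to the x -> y effect, in fixed order.

    mediator: on a directed x->..->y path (adjusting removes part of the
    effect under study).  confounder: a non-collider on an open backdoor
    path (adjusting removes bias).  collider_on_path: a collider on some x–y
    path (adjusting opens it).  risk_factor_only: causes the outcome on
    another pathway (adjusting may improve precision, not bias).
    instrument_like: causes the exposure only.  disconnected otherwise.
    """
    g.check(x, y, v)
    if v in (x, y):
        raise GraphError("covariate must differ from exposure and outcome")
    anc_x = nx.ancestors(g.digraph, x)
    anc_y = nx.ancestors(g.digraph, y)
    desc_x = nx.descendants(g.digraph, x)

    roles = []
    if v in desc_x and v in anc_y:
        roles.append("mediator")
    paths = _enumerate_paths(g, x, y)
    backdoors_open = [p for p in paths if p.kind == "backdoor" and p.open_given_empty]
    if any(
        v in p.nodes[1:-1] and v not in p.colliders() for p in backdoors_open
    ):
        roles.append("confounder")
    if any(v in p.colliders() for p in paths):
        roles.append("collider_on_path")
    if v in anc_y and v not in anc_x and "mediator" not in roles:
        roles.append("risk_factor_only")
    if v in anc_x:
        # "causes the exposure only": every influence of v on y passes through x
        minus_x = g.digraph.copy()
        minus_x.remove_node(x)
        anc_y_without_x = nx.ancestors(minus_x, y) if y in minus_x else set()
        if v not in anc_y_without_x:
            roles.append("instrument_like")
    if not roles:
        return ("disconnected",)
    return tuple(sorted(set(roles), key=ROLE_ORDER.index))


@dataclass(frozen=True)
class AdjustmentReport:
    """Consequences of conditioning on Z for the x -> y effect."""

    x: str
    y: str
    Z: frozenset
    blocked_causal: tuple[PathReport, ...]
    opened: tuple[tuple[PathReport, tuple[str, ...]], ...]

    def __str__(self) -> str:
        lines = [f"conditioning set: {{{', '.join(sorted(self.Z)) or ''}}}"]
        for p in self.blocked_causal:
            lines.append(f"over-control: blocks causal path {p}")
        for p, colliders in self.opened:
            lines.append(
                f"collider bias: opens path {p} via {', '.join(colliders)}"
            )
        if not self.blocked_causal and not self.opened:
            lines.append("no over-control or collider bias introduced")
        return "\n".join(lines)


def adjustment_consequences(g: AnalysisGraph, x: str, y: str, Z) -> AdjustmentReport:
    """Report causal x->y paths blocked by Z (over-control) and previously
    blocked paths opened by conditioning on a collider or collider-descendant
    in Z."""
    Z = frozenset(Z)
    g.check(x, y, *Z)
    if x in Z or y in Z:
        raise GraphError("conditioning set must exclude exposure and outcome")
    paths = _enumerate_paths(g, x, y)
    blocked_causal = tuple(
        p for p in paths if p.kind == "causal" and not p.is_open(g, Z)
    )
    opened = []
    for p in paths:
        if not p.open_given_empty and p.is_open(g, Z):
            responsible = tuple(
                c
                for c in p.colliders()
                if (nx.descendants(g.digraph, c) | {c}) & Z
            )
            opened.append((p, responsible))
    return AdjustmentReport(x, y, Z, blocked_causal, tuple(opened))
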