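"""Translation: resolve every candidate edge through sequential causal criteria.

Each candidate relationship is assessed in both directions under an ordered
battery — temporality (does cause precede effect?), face-validity (is the
relationship plausible given the temporal ordering?), recourse to theory
(is there formal theoretical support? never terminating: absence of theory is
not absence of effect) — culminating in a counterfactual thought experiment in
the potential-outcomes style (would the potential outcomes differ between
counterfactual exposure settings, emulating the study's measurement?).

The verdicts themselves are reviewer input: the criteria are conceptual tools
for structured causal thinking, and this module only records and resolves
them.  An edge whose posited and reverse directions both survive is noted as
bidirectional; one surviving direction is kept (posited or reversed); neither
surviving deletes the edge.  Every verdict and resolution lands in the
decision log.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .graph import (
    Confidence,
    CycleError,
    GraphError,
    MixedGraph,
    Orientation,
    Stage,
    Status,
)
from .log import DecisionLog, pair_subject

__all__ = [
    "Criterion",
    "Verdict",
    "CriteriaAssessment",
    "DirectionOutcome",
    "DirectionResult",
    "Resolution",
    "AssessmentError",
    "assess_direction",
    "resolve_edge",
    "translate_graph",
    "replay",
]


class AssessmentError(GraphError):
    """Malformed or incomplete assessment input."""


class Criterion(str, enum.Enum):
    TEMPORALITY = "temporality"
    FACE_VALIDITY = "face_validity"
    RECOURSE_TO_THEORY = "recourse_to_theory"
    COUNTERFACTUAL = "counterfactual"


CRITERIA_ORDER = (
    Criterion.TEMPORALITY,
    Criterion.FACE_VALIDITY,
    Criterion.RECOURSE_TO_THEORY,
    Criterion.COUNTERFACTUAL,
)

#: "unknown" is a legal verdict only where the scheme tolerates ambiguity:
#: theory may simply be absent, and temporality may be undecidable under
#: contemporaneous measurement (treated as pass-with-low-confidence).
UNKNOWN_OK = {Criterion.RECOURSE_TO_THEORY, Criterion.TEMPORALITY}


class Verdict(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CriteriaAssessment:
    """One reviewer verdict for one criterion on one edge direction."""

    study_id: str
    tail: str
    head: str
    criterion: Criterion
    verdict: Verdict
    rationale: str = ""
    reference: str = ""  # theory citation slot for recourse_to_theory
    reviewer: str = ""
    confidence: Confidence = Confidence.NORMAL
    timestamp: str = ""

    def __post_init__(self):
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        object.__setattr__(self, "verdict", Verdict(self.verdict))
        object.__setattr__(self, "confidence", Confidence(self.confidence))
        if self.verdict is Verdict.UNKNOWN and self.criterion not in UNKNOWN_OK:
            raise AssessmentError(
                f"verdict 'unknown' not permitted for {self.criterion.value} "
                f"({self.tail}->{self.head})"
            )

    @property
    def direction(self) -> tuple[str, str]:
        return (self.tail, self.head)


class DirectionOutcome(str, enum.Enum):
    RETAINED = "retained"
    FAILED_TEMPORALITY = "failed_temporality"
    FAILED_FACE_VALIDITY = "failed_face_validity"
    FAILED_COUNTERFACTUAL = "failed_counterfactual"


@dataclass(frozen=True)
class DirectionResult:
    direction: tuple[str, str]
    outcome: DirectionOutcome
    low_confidence: bool = False


class Resolution(str, enum.Enum):
    RETAIN_POSITED = "retain_posited"
    REVERSE = "reverse"
    BIDIRECTIONAL = "bidirectional"
    DELETE = "delete"


_FAIL_BY_CRITERION = {
    Criterion.TEMPORALITY: DirectionOutcome.FAILED_TEMPORALITY,
    Criterion.FACE_VALIDITY: DirectionOutcome.FAILED_FACE_VALIDITY,
    Criterion.COUNTERFACTUAL: DirectionOutcome.FAILED_COUNTERFACTUAL,
}


def assess_direction(assessments: list[CriteriaAssessment]) -> DirectionResult:
    """Fold one direction's ordered criterion verdicts into an outcome.

    temporality=no or face_validity=no stops the sequence with the
    corresponding failure; recourse_to_theory never terminates; the direction
    is retained only on counterfactual=yes.  temporality=unknown passes but
    flags the direction low-confidence.  Pure function of its input.
    """
    if not assessments:
        raise AssessmentError("no assessments supplied for direction")
    direction = assessments[0].direction
    if any(a.direction != direction for a in assessments):
        raise AssessmentError(f"assessments mix directions: expected {direction}")

    positions = [CRITERIA_ORDER.index(a.criterion) for a in assessments]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise AssessmentError(
            f"criteria out of order or duplicated for {direction[0]}->{direction[1]}"
        )
    if positions != list(range(len(positions))):
        raise AssessmentError(
            f"criteria sequence has gaps for {direction[0]}->{direction[1]}"
        )

    low = any(a.confidence is Confidence.LOW for a in assessments)
    for a in assessments:
        if a.criterion is Criterion.TEMPORALITY and a.verdict is Verdict.UNKNOWN:
            low = True  # contemporaneous measurement: pass, but flag
            continue
        if a.criterion is Criterion.RECOURSE_TO_THEORY:
            continue  # any verdict proceeds
        if a.verdict is Verdict.NO:
            if a is not assessments[-1]:
                raise AssessmentError(
                    f"assessments continue past failed {a.criterion.value} "
                    f"for {direction[0]}->{direction[1]}"
                )
            return DirectionResult(direction, _FAIL_BY_CRITERION[a.criterion], low)
    last = assessments[-1]
    if last.criterion is not Criterion.COUNTERFACTUAL:
        raise AssessmentError(
            f"direction {direction[0]}->{direction[1]} incomplete: "
            f"stops at {last.criterion.value} without a failing verdict"
        )
    return DirectionResult(direction, DirectionOutcome.RETAINED, low)


def resolve_edge(posited: DirectionResult, reverse: DirectionResult) -> Resolution:
    """Combine the two per-direction outcomes into one edge resolution.

    retained/retained -> bidirectional; retained/failed -> retain as posited;
    failed/retained -> reverse; failed/failed -> delete.
    """
    if posited is None or reverse is None:
        raise AssessmentError("both directions must be assessed before resolution")
    p = posited.outcome is DirectionOutcome.RETAINED
    r = reverse.outcome is DirectionOutcome.RETAINED
    if p and r:
        return Resolution.BIDIRECTIONAL
    if p:
        return Resolution.RETAIN_POSITED
    if r:
        return Resolution.REVERSE
    return Resolution.DELETE


@dataclass
class _PairPlan:
    posited: tuple[str, str]
    posited_assessments: list[CriteriaAssessment] = field(default_factory=list)
    reverse_assessments: list[CriteriaAssessment] = field(default_factory=list)


def _group_assessments(graph, assessments, defer):
    plans: dict[frozenset, _PairPlan] = {}
    for e in graph.candidate_edges():
        if e.pair in defer:
            continue
        plans[e.pair] = _PairPlan(posited=(e.tail, e.head))
    for a in assessments:
        pair = frozenset(a.direction)
        plan = plans.get(pair)
        if plan is None:
            if frozenset(pair) in defer or graph.edge(*a.direction) is not None:
                continue
            raise AssessmentError(
                f"assessment for unknown candidate pair {sorted(pair)}"
            )
        if plan.posited == a.direction:
            plan.posited_assessments.append(a)
        else:
            plan.reverse_assessments.append(a)
    # an unassigned pair has no intrinsic direction: take the first-assessed
    # direction as posited
    for pair, plan in plans.items():
        edge = graph.edges[pair]
        if (
            edge.orientation is Orientation.UNASSIGNED
            and not plan.posited_assessments
            and plan.reverse_assessments
        ):
            plan.posited = plan.reverse_assessments[0].direction
            plan.posited_assessments, plan.reverse_assessments = (
                plan.reverse_assessments,
                plan.posited_assessments,
            )
    return plans


def _apply_resolution(g, pair, posited, resolution, confidence):
    edge = g.edges[pair]
    tail, head = posited
    if resolution is Resolution.DELETE:
        del g.edges[pair]
        return
    if resolution is Resolution.REVERSE:
        tail, head = head, tail
    orientation = (
        Orientation.BIDIRECTIONAL
        if resolution is Resolution.BIDIRECTIONAL
        else Orientation.DIRECTED
    )
    del g.edges[pair]
    g.add_edge(tail, head, orientation, Status.RETAINED, confidence, edge.provenance)


def translate_graph(
    ig: MixedGraph,
    assessments: list[CriteriaAssessment],
    log: DecisionLog | None = None,
    defer: set[frozenset] | None = None,
) -> tuple[MixedGraph, DecisionLog]:
    """Resolve every candidate edge of ``ig``; return the DAG and its log.

    Every candidate pair must be covered in both directions (or appear in
    ``defer``, which removes it for later re-assessment in an integrated
    context and logs the deferral).  Deleted edges are removed; surviving
    edges become retained.  The result must be acyclic: a resolution set
    inducing a directed cycle raises :class:`CycleError` naming the cycles.

    Called on an implied graph the result is stage=translated; called on an
    integrated graph carrying fresh candidate edges (pending pairs, reviewer
    nodes) the stage is preserved.
    """
    log = log if log is not None else DecisionLog()
    defer = {frozenset(p) for p in (defer or set())}
    g = ig.copy()

    for pair in sorted(defer, key=sorted):
        if pair in g.edges and g.edges[pair].status is Status.CANDIDATE:
            del g.edges[pair]
            log.append(
                "translation",
                pair_subject(*sorted(pair)),
                "deferred",
                rationale="deferred for re-assessment in the integrated context",
            )

    plans = _group_assessments(g, assessments, defer)
    resolutions = []
    for pair in sorted(plans, key=sorted):
        plan = plans[pair]
        subject = pair_subject(*pair)
        results = {}
        for name, batch in (
            ("posited", plan.posited_assessments),
            ("reverse", plan.reverse_assessments),
        ):
            if not batch:
                raise AssessmentError(
                    f"candidate pair {sorted(pair)} missing {name} direction assessments"
                )
            for a in batch:
                log.append(
                    "translation",
                    subject,
                    "criterion",
                    verdicts={
                        "direction": f"{a.tail}->{a.head}",
                        a.criterion.value: a.verdict.value,
                    },
                    rationale=a.rationale,
                    reference=a.reference,
                    reviewer=a.reviewer,
                )
            result = assess_direction(batch)
            if result.outcome in (
                DirectionOutcome.FAILED_TEMPORALITY,
                DirectionOutcome.FAILED_FACE_VALIDITY,
            ):
                log.append(
                    "translation",
                    subject,
                    "criteria_skipped",
                    verdicts={"direction": f"{batch[0].tail}->{batch[0].head}"},
                    rationale="not assessed — earlier criterion failed",
                )
            results[name] = result
        resolution = resolve_edge(results["posited"], results["reverse"])
        low = results["posited"].low_confidence or results["reverse"].low_confidence
        confidence = Confidence.LOW if low else Confidence.NORMAL
        resolutions.append((pair, plan.posited, resolution, confidence))
        log.append(
            "translation",
            subject,
            "resolution",
            verdicts={
                "posited": f"{plan.posited[0]}->{plan.posited[1]}",
                "posited_outcome": results["posited"].outcome.value,
                "reverse_outcome": results["reverse"].outcome.value,
                "resolution": resolution.value,
                "confidence": confidence.value,
            },
        )

    unresolved = [e for e in g.candidate_edges() if e.pair not in plans]
    if unresolved:
        pairs = sorted(sorted(e.pair) for e in unresolved)
        raise AssessmentError(f"unresolved candidate pairs: {pairs}")

    for pair, posited, resolution, confidence in resolutions:
        _apply_resolution(g, pair, posited, resolution, confidence)

    if g.stage is Stage.IMPLIED:
        g.stage = Stage.TRANSLATED
    if not g.is_acyclic():
        raise CycleError(g.find_cycles())
    g.validate()
    return g, log


def replay(ig: MixedGraph, log: DecisionLog) -> MixedGraph:
    """Re-apply a translation session's logged decisions to its input graph.

    Uses only the ``deferred`` and ``resolution`` entries; reproduces the
    translated graph exactly, which is what makes the log a sufficient audit
    trail.
    """
    g = ig.copy()
    for entry in log.select(stage="translation"):
        if entry.action == "deferred":
            a, b = entry.subject.split(" -- ")
            pair = frozenset((a, b))
            if pair in g.edges:
                del g.edges[pair]
        elif entry.action == "resolution":
            tail, head = entry.verdicts["posited"].split("->")
            pair = frozenset((tail, head))
            _apply_resolution(
                g,
                pair,
                (tail, head),
                Resolution(entry.verdicts["resolution"]),
                Confidence(entry.verdicts.get("confidence", "normal")),
            )
    if g.stage is Stage.IMPLIED:
        g.stage = Stage.TRANSLATED
    if not g.is_acyclic():
        raise CycleError(g.find_cycles())
    return g
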