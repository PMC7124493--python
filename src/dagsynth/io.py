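"""File formats: DAGitty model text, DOT, CSV tables and YAML study records.

DAGitty's textual ``dag { ... }`` syntax is the interchange surface with the
wider DAG ecosystem; layout coordinates are accepted on import (and dropped,
with a notice collected on the graph) but never emitted — layout is
presentation, not structure.  All exports order nodes and edges
lexicographically so output is byte-identical across runs.
"""

from __future__ import annotations

import csv
import io as _io
import re

import yaml

from .graph import (
    Confidence,
    GraphError,
    MixedGraph,
    NodeRef,
    Orientation,
    Stage,
    Status,
)
from .integration import DirectedEdgeRecord, EdgeIndex
from .mapping import StudyRecord
from .translation import CriteriaAssessment

__all__ = [
    "export_dagitty",
    "import_dagitty",
    "DagittyParseError",
    "export_dot",
    "load_study",
    "load_studies",
    "dump_study",
    "assessments_to_csv",
    "assessments_from_csv",
    "index_to_csv",
    "index_from_csv",
]


# -- DAGitty model text ---------------------------------------------------

_ROLE_ANNOTATIONS = {
    "exposure": "exposure",
    "outcome": "outcome",
    "control": "control",
    "mediator": "mediator",
    "instrument": "instrument",
    "reviewer_added": "reviewer_added",
}
_ANNOTATION_ROLES = {v: k for k, v in _ROLE_ANNOTATIONS.items()}


class DagittyParseError(GraphError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"line {line}, column {col}: {message}")
        self.line = line
        self.col = col


def export_dagitty(g: MixedGraph) -> str:
    """Emit DAGitty model text for a translated or integrated graph.

    Implied-stage graphs cannot be represented (unassigned edges have no
    DAGitty arrow), so they are rejected.
    """
    if g.stage is Stage.IMPLIED or any(
        e.orientation is Orientation.UNASSIGNED for e in g.edges.values()
    ):
        raise GraphError("implied-stage graphs with unassigned edges cannot be exported")
    lines = ["dag {"]
    for nid in sorted(g.nodes):
        node = g.nodes[nid]
        attrs = []
        for role in sorted(g.roles.get(nid, ())):
            attrs.append(_ROLE_ANNOTATIONS[role])
        if not node.measured:
            attrs.append("latent")
        if node.label != nid.replace("_", " "):
            attrs.append(f'label="{node.label}"')
        lines.append(f"{nid} [{','.join(attrs)}]" if attrs else nid)
    for pair in sorted(g.edges, key=sorted):
        e = g.edges[pair]
        if e.orientation is Orientation.BIDIRECTIONAL:
            a, b = sorted(e.pair)
            lines.append(f"{a} <-> {b}")
        else:
            lines.append(f"{e.tail} -> {e.head}")
    lines.append("}")
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(r'^(?P<name>"[^"]+"|[A-Za-z0-9_.]+)\s*(?:\[(?P<attrs>[^\]]*)\])?$')
_EDGE_TOKEN_RE = re.compile(r'("[^"]+"|[A-Za-z0-9_.]+|<->|->|<-|\S)')


def _split_attrs(text: str) -> list[str]:
    out, buf, quoted = [], "", False
    for ch in text:
        if ch == '"':
            quoted = not quoted
            buf += ch
        elif ch == "," and not quoted:
            out.append(buf.strip())
            buf = ""
        else:
            buf += ch
    if buf.strip():
        out.append(buf.strip())
    return out


def _unquote(name: str) -> str:
    return name[1:-1] if name.startswith('"') else name


def import_dagitty(text: str) -> MixedGraph:
    """Parse DAGitty model text into a retained-edge graph (stage=translated).

    Known annotations become roles/measured flags; unknown ones (including
    coordinates) are preserved as parse notices on ``graph.notices``.
    """
    g = MixedGraph(stage=Stage.TRANSLATED)
    notices: list[str] = []
    body_seen = False
    closed = False
    pending_nodes: list[tuple[str, list[str], int]] = []
    edge_statements: list[tuple[list[str], int]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not body_seen:
            m = re.match(r"^dag\s*\{(.*)$", line)
            if not m:
                raise DagittyParseError("expected 'dag {'", lineno, 1)
            body_seen = True
            line = m.group(1).strip()
            if not line:
                continue
        if closed:
            raise DagittyParseError("content after closing '}'", lineno, 1)
        if line == "}":
            closed = True
            continue
        if line.endswith("}"):
            line = line[:-1].strip()
            closed = True
        if line.startswith("bb="):
            notices.append("bounding box dropped")
            continue
        if "->" in line or "<-" in line:
            tokens = _EDGE_TOKEN_RE.findall(line)
            edge_statements.append((tokens, lineno))
        else:
            m = _NODE_RE.match(line)
            if not m:
                raise DagittyParseError(f"cannot parse statement: {line!r}", lineno, 1)
            attrs = _split_attrs(m.group("attrs") or "")
            pending_nodes.append((_unquote(m.group("name")), attrs, lineno))

    if not body_seen:
        raise DagittyParseError("no 'dag {' block found", 1, 1)
    if not closed:
        raise DagittyParseError("missing closing '}'", text.count("\n") + 1, 1)

    for name, attrs, lineno in pending_nodes:
        roles: set[str] = set()
        measured = True
        label = ""
        for attr in attrs:
            if attr in ("latent", "unobserved"):
                measured = False
            elif attr in _ANNOTATION_ROLES:
                roles.add(_ANNOTATION_ROLES[attr])
            elif attr.startswith("label="):
                label = attr.split("=", 1)[1].strip('"')
            elif attr.startswith("pos="):
                notices.append(f"coordinates on {name} dropped")
            elif attr == "adjusted":
                notices.append(f"adjusted flag on {name} preserved as note")
            elif attr:
                notices.append(f"unknown annotation {attr!r} on {name} preserved as note")
        try:
            g.add_node(NodeRef(id=name, label=label, measured=measured), roles=roles or None)
        except GraphError as exc:
            raise DagittyParseError(str(exc), lineno, 1) from exc

    def ensure(name: str) -> str:
        if name not in g.nodes:
            g.add_node(NodeRef(id=name))
        return name

    for tokens, lineno in edge_statements:
        if len(tokens) < 3 or len(tokens) % 2 == 0:
            raise DagittyParseError(
                f"malformed edge statement: {' '.join(tokens)!r}", lineno, 1
            )
        for i in range(1, len(tokens), 2):
            op = tokens[i]
            a, b = _unquote(tokens[i - 1]), _unquote(tokens[i + 1])
            col = 1 + sum(len(t) + 1 for t in tokens[:i])
            if op not in ("->", "<-", "<->"):
                raise DagittyParseError(f"malformed arrow {op!r}", lineno, col)
            if a == b:
                raise DagittyParseError(f"self-loop on {a!r}", lineno, col)
            ensure(a), ensure(b)
            try:
                if op == "<->":
                    x, y = sorted((a, b))
                    g.add_edge(x, y, Orientation.BIDIRECTIONAL, Status.RETAINED)
                elif op == "->":
                    g.add_edge(a, b, Orientation.DIRECTED, Status.RETAINED)
                else:
                    g.add_edge(b, a, Orientation.DIRECTED, Status.RETAINED)
            except GraphError as exc:
                raise DagittyParseError(str(exc), lineno, col) from exc

    g.notices = notices  # type: ignore[attr-defined]
    g.validate()
    return g


# -- DOT ------------------------------------------------------------------

def export_dot(g: MixedGraph, name: str = "g") -> str:
    """Standard DOT digraph; bidirectional edges carry dir=both, unassigned
    saturation edges dir=none."""
    lines = [f"digraph {name} {{"]
    for nid in sorted(g.nodes):
        attrs = [f'label="{g.nodes[nid].label}"']
        if not g.nodes[nid].measured:
            attrs.append('style="dashed"')
        lines.append(f'  "{nid}" [{", ".join(attrs)}];')
    for pair in sorted(g.edges, key=sorted):
        e = g.edges[pair]
        if e.orientation is Orientation.BIDIRECTIONAL:
            a, b = sorted(e.pair)
            lines.append(f'  "{a}" -> "{b}" [dir=both];')
        elif e.orientation is Orientation.UNASSIGNED:
            a, b = sorted(e.pair)
            lines.append(f'  "{a}" -> "{b}" [dir=none, style=dashed];')
        else:
            lines.append(f'  "{e.tail}" -> "{e.head}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# -- study record documents ----------------------------------------------

_STUDY_KEYS = {
    "study_id",
    "citation",
    "exposures",
    "outcomes",
    "controls",
    "mediators",
    "instruments",
    "labels",
    "aliases",
}


def _study_from_dict(doc: dict) -> StudyRecord:
    if not isinstance(doc, dict):
        raise GraphError("study document must be a mapping")
    unknown = set(doc) - _STUDY_KEYS
    if unknown:
        raise GraphError(f"unknown study-record keys: {sorted(unknown)}")
    for key in ("study_id",):
        if key not in doc:
            raise GraphError(f"study record missing required key {key!r}")
    return StudyRecord(
        study_id=doc["study_id"],
        citation=doc.get("citation", ""),
        exposures=list(doc.get("exposures", [])),
        outcomes=list(doc.get("outcomes", [])),
        controls=list(doc.get("controls", [])),
        mediators=[tuple(m) for m in doc.get("mediators", [])],
        instruments=[tuple(i) for i in doc.get("instruments", [])],
        labels=dict(doc.get("labels", {})),
        aliases={k: list(v) for k, v in doc.get("aliases", {}).items()},
    )


def load_studies(path) -> list[StudyRecord]:
    """Read key-value study documents (YAML, one document per study)."""
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    return [_study_from_dict(d) for d in docs if d is not None]


def load_study(path) -> StudyRecord:
    studies = load_studies(path)
    if len(studies) != 1:
        raise GraphError(f"expected exactly one study document in {path}")
    return studies[0]


def dump_study(record: StudyRecord) -> str:
    doc = {
        "study_id": record.study_id,
        "citation": record.citation,
        "exposures": list(record.exposures),
        "outcomes": list(record.outcomes),
        "controls": list(record.controls),
        "mediators": [list(m) for m in record.mediators],
        "instruments": [list(i) for i in record.instruments],
    }
    if record.labels:
        doc["labels"] = dict(record.labels)
    if record.aliases:
        doc["aliases"] = {k: list(v) for k, v in record.aliases.items()}
    return yaml.safe_dump(doc, sort_keys=False)


# -- assessments CSV ------------------------------------------------------

ASSESSMENT_COLUMNS = [
    "study_id",
    "tail",
    "head",
    "criterion",
    "verdict",
    "rationale",
    "reference",
    "reviewer",
    "confidence",
    "timestamp",
]


def assessments_to_csv(assessments) -> str:
    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=ASSESSMENT_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for a in assessments:
        writer.writerow(
            {
                "study_id": a.study_id,
                "tail": a.tail,
                "head": a.head,
                "criterion": a.criterion.value,
                "verdict": a.verdict.value,
                "rationale": a.rationale,
                "reference": a.reference,
                "reviewer": a.reviewer,
                "confidence": a.confidence.value,
                "timestamp": a.timestamp,
            }
        )
    return buf.getvalue()


def assessments_from_csv(text: str) -> list[CriteriaAssessment]:
    reader = csv.DictReader(_io.StringIO(text))
    if reader.fieldnames != ASSESSMENT_COLUMNS:
        raise GraphError(
            f"assessment CSV columns must be exactly {ASSESSMENT_COLUMNS}, "
            f"got {reader.fieldnames}"
        )
    return [
        CriteriaAssessment(
            study_id=row["study_id"],
            tail=row["tail"],
            head=row["head"],
            criterion=row["criterion"],
            verdict=row["verdict"],
            rationale=row["rationale"],
            reference=row["reference"],
            reviewer=row["reviewer"],
            confidence=row["confidence"] or "normal",
            timestamp=row["timestamp"],
        )
        for row in reader
    ]


# -- edge index CSV -------------------------------------------------------

INDEX_COLUMNS = ["tail", "head", "bidirectional", "confidence", "provenance", "notes"]
DELETION_COLUMNS = ["node_a", "node_b", "provenance"]


def index_to_csv(index: EdgeIndex) -> tuple[str, str]:
    """Serialise (records table, deletions table)."""
    rec_buf = _io.StringIO()
    w = csv.DictWriter(rec_buf, fieldnames=INDEX_COLUMNS, lineterminator="\n")
    w.writeheader()
    for pair in sorted(index.records, key=sorted):
        r = index.records[pair]
        w.writerow(
            {
                "tail": r.tail,
                "head": r.head,
                "bidirectional": str(r.bidirectional).lower(),
                "confidence": r.confidence.value,
                "provenance": ";".join(sorted(r.provenance)),
                "notes": r.notes,
            }
        )
    del_buf = _io.StringIO()
    w = csv.DictWriter(del_buf, fieldnames=DELETION_COLUMNS, lineterminator="\n")
    w.writeheader()
    for pair in sorted(index.deletions, key=sorted):
        a, b = sorted(pair)
        w.writerow(
            {
                "node_a": a,
                "node_b": b,
                "provenance": ";".join(sorted(index.deletions[pair])),
            }
        )
    return rec_buf.getvalue(), del_buf.getvalue()


def index_from_csv(records_text: str, deletions_text: str = "") -> EdgeIndex:
    index = EdgeIndex()
    reader = csv.DictReader(_io.StringIO(records_text))
    if reader.fieldnames != INDEX_COLUMNS:
        raise GraphError(f"index CSV columns must be exactly {INDEX_COLUMNS}")
    for row in reader:
        index.add_record(
            DirectedEdgeRecord(
                tail=row["tail"],
                head=row["head"],
                bidirectional=row["bidirectional"] == "true",
                confidence=Confidence(row["confidence"]),
                provenance=frozenset(row["provenance"].split(";")),
                notes=row["notes"],
            )
        )
    if deletions_text.strip():
        reader = csv.DictReader(_io.StringIO(deletions_text))
        if reader.fieldnames != DELETION_COLUMNS:
            raise GraphError(f"deletions CSV columns must be exactly {DELETION_COLUMNS}")
        for row in reader:
            for sid in row["provenance"].split(";"):
                index.register_deletion(frozenset((row["node_a"], row["node_b"])), sid)
    return index
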