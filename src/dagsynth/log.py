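"""Append-only decision log.

Every graph mutation in a session — criterion verdict, edge resolution,
deferral, index mutation, synthesis, recombination — appends at least one
entry, so the final graphs can be audited and replayed from their inputs.
Entries carry a strictly increasing sequence number.  The timestamp comes
from an injectable clock; the default clock returns an empty string so that
serialised logs are byte-identical across runs on identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable

__all__ = ["DecisionLogEntry", "DecisionLog"]

STAGES = ("mapping", "translation", "synthesis", "recombination")


@dataclass(frozen=True)
class DecisionLogEntry:
    seq: int
    stage: str  # mapping | translation | synthesis | recombination
    subject: str  # "a -- b" edge pair or a node id
    action: str
    verdicts: dict = field(default_factory=dict)
    rationale: str = ""
    reference: str = ""
    reviewer: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def pair_subject(a: str, b: str) -> str:
    x, y = sorted((a, b))
    return f"{x} -- {y}"


class DecisionLog:
    """Ordered, append-only collection of :class:`DecisionLogEntry`."""

    def __init__(self, clock: Callable[[], str] | None = None, reviewer: str = ""):
        self.entries: list[DecisionLogEntry] = []
        self._clock = clock or (lambda: "")
        self.reviewer = reviewer

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def append(
        self,
        stage: str,
        subject: str,
        action: str,
        verdicts: dict | None = None,
        rationale: str = "",
        reference: str = "",
        reviewer: str = "",
    ) -> DecisionLogEntry:
        if stage not in STAGES:
            raise ValueError(f"unknown log stage: {stage!r}")
        entry = DecisionLogEntry(
            seq=len(self.entries) + 1,
            stage=stage,
            subject=subject,
            action=action,
            verdicts=dict(verdicts or {}),
            rationale=rationale,
            reference=reference,
            reviewer=reviewer or self.reviewer,
            timestamp=self._clock(),
        )
        self.entries.append(entry)
        return entry

    # -- persistence (newline-delimited JSON; append-only safe) -----------

    def dumps(self) -> str:
        return "".join(e.to_json() + "\n" for e in self.entries)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "DecisionLog":
        log = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            log.entries.append(DecisionLogEntry(**d))
        seqs = [e.seq for e in log.entries]
        if seqs != sorted(seqs) or len(set(seqs)) != len(seqs):
            raise ValueError("decision log sequence numbers not strictly increasing")
        return log

    @classmethod
    def load(cls, path) -> "DecisionLog":
        with open(path) as fh:
            return cls.loads(fh.read())

    def select(self, stage: str | None = None, action: str | None = None) -> Iterable[DecisionLogEntry]:
        for e in self.entries:
            if stage is not None and e.stage != stage:
                continue
            if action is not None and e.action != action:
                continue
            yield e
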