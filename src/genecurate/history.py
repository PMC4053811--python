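"""Edit history: an ordered, attributed, persistent log supporting undo,
redo and point-in-time reconstruction.

Undo is snapshot-based: every entry stores full pre- and post-edit images
of the annotation state (genes, alterations, id counters).  Cascading
edits — a gene vanishing with its last transcript, isoform regrouping —
make algebraic inverses error-prone, whereas snapshots restore the whole
cascade as one unit and make "how did this look after edit k" a constant-
time lookup.  Annotation states are small (a curated region, not a whole
genome), so the cost is negligible.

The journal is a newline-delimited JSON log, one record per line, with a
versioned header — human-diffable and append-only: an undo appends an
``undo`` marker rather than rewriting anything, and a new edit after an
undo implicitly truncates the redo branch on replay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .model import GenecurateError, RangeError

JOURNAL_FORMAT = "genecurate-journal"
JOURNAL_VERSION = 1


class JournalError(GenecurateError):
    """The journal file is corrupt; names the first bad record."""


@dataclass
class HistoryEntry:
    """One applied edit: operation, author, time and state images."""

    seq: int
    op: str
    user: str
    timestamp: str
    pre_state: dict
    post_state: dict
    message: str = ""

    def to_dict(self) -> dict:
        return {"record": "entry", "seq": self.seq, "op": self.op,
                "user": self.user, "timestamp": self.timestamp,
                "message": self.message,
                "pre_state": self.pre_state, "post_state": self.post_state}

    @classmethod
    def from_dict(cls, d: dict) -> "HistoryEntry":
        return cls(d["seq"], d["op"], d["user"], d["timestamp"],
                   d["pre_state"], d["post_state"], d.get("message", ""))


@dataclass
class History:
    """Gapless, append-only log with an undo cursor.

    ``position`` counts currently-applied entries: entries beyond it form
    the redo branch.  Recording a new entry truncates that branch.
    """

    initial_state: dict = field(default_factory=dict)
    entries: list[HistoryEntry] = field(default_factory=list)
    position: int = 0

    @property
    def latest(self) -> int:
        return len(self.entries)

    def next_seq(self) -> int:
        return self.position + 1

    def record(self, entry: HistoryEntry) -> None:
        del self.entries[self.position:]  # truncate redo branch
        if entry.seq != len(self.entries) + 1:
            raise ValueError(
                f"entry seq {entry.seq} breaks gapless numbering "
                f"(expected {len(self.entries) + 1})")
        self.entries.append(entry)
        self.position = len(self.entries)

    @property
    def can_undo(self) -> bool:
        return self.position > 0

    @property
    def can_redo(self) -> bool:
        return self.position < len(self.entries)

    def undo(self) -> Optional[dict]:
        """State to restore, or ``None`` (no-op) on empty history."""
        if not self.can_undo:
            return None
        entry = self.entries[self.position - 1]
        self.position -= 1
        return entry.pre_state

    def redo(self) -> Optional[dict]:
        if not self.can_redo:
            return None
        entry = self.entries[self.position]
        self.position += 1
        return entry.post_state

    def state_at(self, n: int) -> dict:
        """Annotation state right after entry ``n`` (0 = initial load).

        A read-only reconstruction; the current state is untouched.
        """
        if not (0 <= n <= self.latest):
            raise RangeError(f"history has entries 0..{self.latest}, not {n}")
        if n == 0:
            return self.initial_state
        return self.entries[n - 1].post_state

    def listing(self) -> list[tuple[int, str, str, str]]:
        """(seq, op, user, timestamp) for display, applied entries first."""
        return [(e.seq, e.op, e.user, e.timestamp) for e in self.entries]

    # -- journal persistence ------------------------------------------------

    def journal_records(self) -> list[dict]:
        """The full record stream that reproduces this history on replay."""
        records: list[dict] = [
            {"record": "header", "format": JOURNAL_FORMAT,
             "version": JOURNAL_VERSION},
            {"record": "initial", "state": self.initial_state},
        ]
        records.extend(e.to_dict() for e in self.entries)
        records.extend({"record": "undo"}
                       for _ in range(len(self.entries) - self.position))
        return records

    def journal_write(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.journal_records():
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    @classmethod
    def journal_load(cls, path) -> "History":
        hist: Optional[History] = None
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines:
            raise JournalError("record 1: empty journal")
        for i, line in enumerate(lines, start=1):
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise JournalError(f"record {i}: not valid JSON ({exc.msg})")
            kind = rec.get("record")
            if i == 1:
                if (kind != "header" or rec.get("format") != JOURNAL_FORMAT
                        or rec.get("version") != JOURNAL_VERSION):
                    raise JournalError(f"record 1: bad or missing header")
                continue
            if kind == "initial":
                if hist is not None:
                    raise JournalError(f"record {i}: duplicate initial state")
                hist = cls(initial_state=rec["state"])
                continue
            if hist is None:
                raise JournalError(f"record {i}: no initial state before {kind!r}")
            if kind == "entry":
                try:
                    hist.record(HistoryEntry.from_dict(rec))
                except (KeyError, ValueError) as exc:
                    raise JournalError(f"record {i}: bad entry ({exc})")
            elif kind == "undo":
                if hist.undo() is None:
                    raise JournalError(f"record {i}: undo with empty history")
            elif kind == "redo":
                if hist.redo() is None:
                    raise JournalError(f"record {i}: redo with nothing undone")
            else:
                raise JournalError(f"record {i}: unknown record kind {kind!r}")
        if hist is None:
            raise JournalError("record 2: missing initial state")
        return hist

    def current_state(self) -> dict:
        if self.position == 0:
            return self.initial_state
        return self.entries[self.position - 1].post_state
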