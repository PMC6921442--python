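"""Synthetic patient records: seed-sequence generation and mutation
operations with full provenance.

Real patient records suitable for benchmarking aligners are hard to come
by, so evaluation data is built in two steps:

1. :func:`generate_seed_sequence` draws a *seed* record emulating the
   clinical-encounter scenarios seen in real diagnosis extracts:
   single-diagnosis days, multi-diagnosis days (one or several visits
   merged into one daily event), a chronic-style code that recurs across
   many days, and an acute-style code that occurs once.

2. :func:`synthesize_benchmark` derives mutated *synthetic* records by
   applying deleting / updating / switching operations at the daily-event
   or event-block level (block length = max(2, floor(n/10))).  Every
   random choice is recorded in an :class:`Operation`, so each synthetic
   record carries a replayable provenance log and an index map from
   synthetic positions back to seed positions — the ground truth from
   which reference alignments are built.

The default benchmark design applies 20 operation combinations per seed,
from a single daily deletion ("x") up to a block delete + block update +
block switch ("X U S").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .records_io import DailyEvent, EventSequence, _synthetic_dates

__all__ = [
    "Operation",
    "SyntheticRecord",
    "SequenceProfile",
    "block_size",
    "apply_operation",
    "replay_operation",
    "synthesize_benchmark",
    "generate_seed_sequence",
    "default_vocabulary",
    "DEFAULT_DESIGN",
]

#: the 20 operation-combination labels of the default benchmark design.
#: lower case = daily-event level, upper case = event-block level;
#: x/X delete, u/U update, s/S switch.
DEFAULT_DESIGN: tuple[str, ...] = (
    "x", "x x", "u", "u u", "s", "s s", "x u", "x s", "u s", "x u s",
    "X", "X X", "U", "U U", "S", "S S", "X U", "X S", "U S", "X U S",
)

_LABEL_TO_OP = {
    "x": ("delete", "daily"), "u": ("update", "daily"), "s": ("switch", "daily"),
    "X": ("delete", "block"), "U": ("update", "block"), "S": ("switch", "block"),
}


def default_vocabulary(size: int = 582) -> tuple[str, ...]:
    """Synthetic code universe; 582 mirrors a grouped diagnosis vocabulary."""
    width = len(str(size))
    return tuple(f"C{k:0{width}d}" for k in range(1, size + 1))


def block_size(n: int) -> int:
    """Event-block length for a sequence of n daily events: max(2, floor(n/10))."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    return max(2, n // 10)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class Operation:
    """One applied mutation, recorded precisely enough to replay it.

    ``positions`` holds 1-based positions in the sequence the operation
    was applied to: ints at daily level, (start, end) inclusive intervals
    at block level; switch records two of them.  ``details`` captures the
    random content choices (replacement codes / events).
    """

    kind: str   # delete | update | switch
    level: str  # daily | block
    positions: tuple[Any, ...]
    details: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "level": self.level,
            "positions": [list(p) if isinstance(p, tuple) else p for p in self.positions],
            "details": self.details,
        }

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "Operation":
        return cls(
            obj["kind"],
            obj["level"],
            tuple(tuple(p) if isinstance(p, list) else p for p in obj["positions"]),
            obj.get("details", {}),
        )


@dataclass(frozen=True)
class SyntheticRecord:
    """A mutated sequence plus its ground-truth provenance.

    ``index_map[j]`` (0-based list over synthetic positions) gives the
    1-based seed position that synthetic position j+1 descends from, or
    ``None`` for positions with no seed origin.  Updated and switched
    positions keep their positional identity — their *content* changed or
    moved, but the calendar slot still descends from the same seed slot —
    so only deletions alter the map.
    """

    sequence: EventSequence
    provenance: tuple[Operation, ...]
    index_map: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.index_map) != len(self.sequence):
            raise ValueError("index_map must have one entry per synthetic position")


def _with_events(seq: EventSequence, events: Sequence[DailyEvent], pid: str | None = None) -> EventSequence:
    return EventSequence(
        pid or seq.patient_id, events, _synthetic_dates(len(events))
    )


def replay_operation(seq: EventSequence, op: Operation) -> EventSequence:
    """Deterministically re-apply a recorded operation."""
    events = list(seq.events)
    n = len(events)

    def check_pos(p: int) -> None:
        if not 1 <= p <= n:
            raise ValueError(f"operation position {p} outside sequence of length {n}")

    if op.kind == "delete":
        if op.level == "daily":
            (p,) = op.positions
            check_pos(p)
            del events[p - 1]
        else:
            ((s, e),) = op.positions
            check_pos(s), check_pos(e)
            del events[s - 1 : e]
    elif op.kind == "update":
        if op.level == "daily":
            (p,) = op.positions
            check_pos(p)
            codes = set(events[p - 1].codes)
            old = op.details["old_code"]
            if old not in codes:
                raise ValueError(f"update replay: code {old!r} absent at position {p}")
            codes.discard(old)
            if op.details["action"] == "replace":
                codes.add(op.details["new_code"])
            events[p - 1] = DailyEvent(codes)
        else:
            ((s, e),) = op.positions
            check_pos(s), check_pos(e)
            replacement = [DailyEvent(c) for c in op.details["replacement"]]
            if len(replacement) != e - s + 1:
                raise ValueError("update replay: replacement length differs from block length")
            events[s - 1 : e] = replacement
    elif op.kind == "switch":
        if op.level == "daily":
            p, q = op.positions
            check_pos(p), check_pos(q)
            events[p - 1], events[q - 1] = events[q - 1], events[p - 1]
        else:
            (s1, e1), (s2, e2) = sorted(op.positions)
            check_pos(s1), check_pos(e2)
            if e1 >= s2:
                raise ValueError("switch replay: blocks overlap")
            if e1 - s1 != e2 - s2:
                raise ValueError("switch replay: blocks differ in length")
            b1, b2 = events[s1 - 1 : e1], events[s2 - 1 : e2]
            events[s1 - 1 : e1], events[s2 - 1 : e2] = b2, b1
    else:
        raise ValueError(f"unknown operation kind {op.kind!r}")
    return _with_events(seq, events)


def _draw_event(rng: np.random.Generator, vocab: Sequence[str], n_codes: int) -> DailyEvent:
    n_codes = min(n_codes, len(vocab))
    picked = rng.choice(len(vocab), size=n_codes, replace=False)
    return DailyEvent(vocab[int(k)] for k in picked)


def apply_operation(
    seq: EventSequence,
    op_kind: str,
    level: str,
    rng: np.random.Generator | int | None,
    vocab: Sequence[str],
    block: int | None = None,
) -> tuple[EventSequence, Operation]:
    """Apply one randomly-parameterized operation; return (mutated, record).

    ``block`` overrides the block length (default max(2, floor(n/10)) of
    the *current* sequence).  The returned :class:`Operation` captures
    every random choice, so :func:`replay_operation` reproduces the
    mutation exactly.
    """
    rng = _as_rng(rng)
    n = len(seq)
    if op_kind not in ("delete", "update", "switch"):
        raise ValueError(f"unknown operation kind {op_kind!r}")
    if level not in ("daily", "block"):
        raise ValueError(f"unknown operation level {level!r}")
    bs = block if block is not None else block_size(n)

    if level == "daily":
        if op_kind == "delete":
            if n < 2:
                raise ValueError("daily delete needs a sequence of >= 2 events")
            p = int(rng.integers(1, n + 1))
            op = Operation("delete", "daily", (p,))
        elif op_kind == "update":
            p = int(rng.integers(1, n + 1))
            codes = seq[p - 1].codes
            can_remove = len(codes) > 1
            remove = can_remove and bool(rng.integers(0, 2))
            old = str(rng.choice(sorted(codes)))
            if remove:
                op = Operation("update", "daily", (p,), {"action": "remove", "old_code": old})
            else:
                pool = [c for c in vocab if c not in codes]
                if not pool:
                    raise ValueError("vocabulary exhausted: no replacement code available")
                new = str(rng.choice(pool))
                op = Operation(
                    "update", "daily", (p,),
                    {"action": "replace", "old_code": old, "new_code": new},
                )
        else:  # switch
            if n < 2:
                raise ValueError("daily switch needs a sequence of >= 2 events")
            p, q = (int(x) + 1 for x in rng.choice(n, size=2, replace=False))
            op = Operation("switch", "daily", (min(p, q), max(p, q)))
    else:  # block level
        if op_kind == "delete":
            if n < bs + 1:
                raise ValueError(
                    f"block delete needs >= {bs + 1} events (block length {bs}), got {n}"
                )
            s = int(rng.integers(1, n - bs + 2))
            op = Operation("delete", "block", ((s, s + bs - 1),))
        elif op_kind == "update":
            if n < bs:
                raise ValueError(f"block update needs >= {bs} events, got {n}")
            s = int(rng.integers(1, n - bs + 2))
            replacement = [
                _draw_event(rng, vocab, len(seq[k].codes)) for k in range(s - 1, s - 1 + bs)
            ]
            op = Operation(
                "update", "block", ((s, s + bs - 1),),
                {"replacement": [sorted(ev.codes) for ev in replacement]},
            )
        else:  # switch block: two disjoint equal-length blocks
            if n < 2 * bs:
                raise ValueError(
                    f"block switch needs >= {2 * bs} events (two disjoint blocks of {bs}), got {n}"
                )
            # draw two disjoint starts uniformly over the valid pairs
            s1 = int(rng.integers(1, n - 2 * bs + 2))
            s2 = int(rng.integers(s1 + bs, n - bs + 2))
            op = Operation("switch", "block", ((s1, s1 + bs - 1), (s2, s2 + bs - 1)))
    return replay_operation(seq, op), op


def _update_index_map(index_map: list[int | None], op: Operation) -> list[int | None]:
    """Only deletions alter positional descent; updates/switches keep it."""
    if op.kind != "delete":
        return index_map
    if op.level == "daily":
        (p,) = op.positions
        return index_map[: p - 1] + index_map[p:]
    ((s, e),) = op.positions
    return index_map[: s - 1] + index_map[e:]


def synthesize_benchmark(
    seed: EventSequence,
    design: Sequence[str] = DEFAULT_DESIGN,
    rng: np.random.Generator | int | None = None,
    vocab: Sequence[str] | None = None,
) -> list[SyntheticRecord]:
    """Derive one synthetic record per design row.

    Each row is a whitespace-separated combination of operation labels
    (``x u s`` daily, ``X U S`` block) applied left-to-right, each to the
    already-mutated sequence; positions are re-drawn per operation.
    """
    rng = _as_rng(rng)
    vocab = tuple(vocab) if vocab is not None else default_vocabulary()
    records = []
    for row, label in enumerate(design, start=1):
        parts = label.split()
        if not parts or any(p not in _LABEL_TO_OP for p in parts):
            raise ValueError(f"design row {row}: unknown operation label {label!r}")
        seq = seed
        index_map: list[int | None] = list(range(1, len(seed) + 1))
        ops = []
        for part in parts:
            kind, level = _LABEL_TO_OP[part]
            seq, op = apply_operation(seq, kind, level, rng, vocab)
            index_map = _update_index_map(index_map, op)
            ops.append(op)
        seq = _with_events(seq, seq.events, pid=f"{seed.patient_id}-syn{row:02d}")
        records.append(SyntheticRecord(seq, tuple(ops), tuple(index_map)))
    return records


@dataclass(frozen=True)
class SequenceProfile:
    """Tunable shape of a generated seed sequence.

    ``multi_code_fraction`` — fraction of days carrying more than one
    base diagnosis (emulating multi-diagnosis and multi-visit days);
    ``max_codes_per_day`` — cap on base codes per day;
    ``chronic_days`` — days on which the recurring chronic-style code
    appears (default max(2, round(0.3·n)));
    ``acute_days`` — days on which the isolated acute-style code appears.
    """

    multi_code_fraction: float = 0.4
    max_codes_per_day: int = 3
    chronic_days: int | None = None
    acute_days: int = 1

    def resolved_chronic_days(self, n_events: int) -> int:
        k = self.chronic_days if self.chronic_days is not None else max(2, round(0.3 * n_events))
        if k > n_events:
            raise ValueError(
                f"chronic recurrence {k} exceeds sequence length {n_events}"
            )
        if k < 1:
            raise ValueError("chronic_days must be >= 1")
        return k


def generate_seed_sequence(
    n_events: int,
    vocab: Sequence[str] | None = None,
    profile: SequenceProfile = SequenceProfile(),
    rng: np.random.Generator | int | None = None,
    patient_id: str = "seed",
) -> EventSequence:
    """Draw a seed patient sequence of ``n_events`` daily events.

    Guarantees (for any valid profile): at least one multi-code day, one
    code recurring on ``chronic_days`` distinct days, and one code
    occurring exactly once.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    vocab = tuple(vocab) if vocab is not None else default_vocabulary()
    if len(vocab) < 4:
        raise ValueError("vocabulary needs >= 4 codes")
    rng = _as_rng(rng)
    chronic_k = profile.resolved_chronic_days(n_events)
    if profile.acute_days > n_events:
        raise ValueError("acute_days exceeds sequence length")

    chronic_code, acute_code = (vocab[int(k)] for k in rng.choice(len(vocab), 2, replace=False))
    base_vocab = [c for c in vocab if c not in (chronic_code, acute_code)]
    chronic_at = set(int(k) for k in rng.choice(n_events, chronic_k, replace=False))
    acute_at = set(int(k) for k in rng.choice(n_events, profile.acute_days, replace=False))

    events = []
    for day in range(n_events):
        if rng.random() < profile.multi_code_fraction and profile.max_codes_per_day >= 2:
            k = int(rng.integers(2, profile.max_codes_per_day + 1))
        else:
            k = 1
        codes = set(str(rng.choice(base_vocab)) for _ in range(k))  # dupes collapse
        if day in chronic_at:
            codes.add(chronic_code)
        if day in acute_at:
            codes.add(acute_code)
        events.append(DailyEvent(codes))

    # a lone single-code day universe can occur by chance; force the
    # multi-diagnosis scenario the generator promises
    if all(len(ev) == 1 for ev in events):
        day = int(rng.integers(0, n_events))
        extra = str(rng.choice([c for c in base_vocab if c not in events[day].codes]))
        events[day] = DailyEvent(set(events[day].codes) | {extra})

    return EventSequence(patient_id, events, _synthetic_dates(n_events))
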