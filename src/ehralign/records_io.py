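"""Domain types and I/O for patient event sequences.

A patient medical record is modelled as an ordered sequence of *daily
events*: for each calendar date with at least one clinical encounter, the
set of all diagnosis codes recorded that day.  The daily event is the
atomic symbol of the alignment alphabet — alignment never looks inside a
day's ordering (EHR extracts do not record intra-day order) and never at
the time gap between days, only at the order of days.

Two interchange formats are supported:

* delimited text (CSV) with columns ``patient_id,date,code`` — one code per
  row, the way EHR diagnosis extracts usually arrive.  Rows sharing a
  ``(patient_id, date)`` are merged into one daily event (set union of
  their codes), so multiple visits on one day collapse into a single
  symbol.
* JSON lines — one object per patient with an explicit ordered event
  array, which preserves authored sequences exactly (including sequences
  without dates).
"""

from __future__ import annotations

import csv
import datetime
import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "DailyEvent",
    "EventSequence",
    "FormatError",
    "read_sequences",
    "write_sequences",
    "group_code",
]

#: separator used for multi-code events in delimited output
CODE_SEPARATOR = "|"


class FormatError(ValueError):
    """Raised when an input stream violates the interchange format."""


@dataclass(frozen=True)
class DailyEvent:
    """The set of diagnosis codes observed for one patient on one date.

    Codes have set semantics: duplicates collapse, order is irrelevant.
    An empty event is meaningless (a day with no diagnosis is simply not
    part of the sequence), so ``codes`` must be non-empty.
    """

    codes: frozenset[str]

    def __init__(self, codes: Iterable[str]) -> None:
        fs = frozenset(codes)
        if not fs:
            raise ValueError("a DailyEvent must contain at least one code")
        if any(not c for c in fs):
            raise ValueError("diagnosis codes must be non-empty strings")
        object.__setattr__(self, "codes", fs)

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __repr__(self) -> str:  # stable order for readable diffs
        return "{" + ",".join(sorted(self.codes)) + "}"


@dataclass(frozen=True)
class EventSequence:
    """An ordered sequence of daily events for one patient.

    ``dates``, when present, must be strictly increasing and pair
    one-to-one with ``events``.  Dates are carried for provenance and
    serialization only; the aligners consume event *order*, never
    inter-event time gaps.
    """

    patient_id: str
    events: tuple[DailyEvent, ...]
    dates: tuple[datetime.date, ...] | None = None

    def __init__(
        self,
        patient_id: str,
        events: Sequence[DailyEvent],
        dates: Sequence[datetime.date] | None = None,
    ) -> None:
        events = tuple(events)
        if not events:
            raise ValueError(f"patient {patient_id!r}: a sequence needs >= 1 daily event")
        if dates is not None:
            dates = tuple(dates)
            if len(dates) != len(events):
                raise ValueError(
                    f"patient {patient_id!r}: {len(dates)} dates for {len(events)} events"
                )
            if any(a >= b for a, b in zip(dates, dates[1:])):
                raise ValueError(f"patient {patient_id!r}: dates must be strictly increasing")
        object.__setattr__(self, "patient_id", patient_id)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "dates", dates)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i: int) -> DailyEvent:
        return self.events[i]


def group_code(code: str) -> str:
    """Truncate a diagnosis code at its first period.

    Collapses fine-grained codes into their broader disease category
    (e.g. ``"195.1"`` becomes ``"195"``); codes without a period are
    returned unchanged.  This is an explicit, opt-in preprocessing step.
    """
    if not code:
        raise ValueError("cannot group an empty diagnosis code")
    head = code.split(".", 1)[0]
    if not head:
        raise ValueError(f"malformed diagnosis code {code!r}: nothing before the period")
    return head


def _parse_date(raw: str, where: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw)
    except ValueError as exc:
        raise FormatError(f"{where}: unparseable date {raw!r}") from exc


def _read_csv(stream: IO[str]) -> list[EventSequence]:
    reader = csv.DictReader(stream)
    required = {"patient_id", "date", "code"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FormatError(
            f"delimited input needs header columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    # (patient, date) -> set of codes; patients keep file order of first mention
    per_day: dict[str, dict[datetime.date, set[str]]] = {}
    for lineno, row in enumerate(reader, start=2):
        pid = (row["patient_id"] or "").strip()
        raw_code = (row["code"] or "").strip()
        if not pid:
            raise FormatError(f"row {lineno}: empty patient_id")
        if not raw_code:
            raise FormatError(f"row {lineno}: empty code field for patient {pid!r}")
        date = _parse_date((row["date"] or "").strip(), f"row {lineno}")
        codes = {c.strip() for c in raw_code.split(CODE_SEPARATOR) if c.strip()}
        if not codes:
            raise FormatError(f"row {lineno}: empty code field for patient {pid!r}")
        per_day.setdefault(pid, {}).setdefault(date, set()).update(codes)

    out = []
    for pid, by_date in per_day.items():
        dates = sorted(by_date)
        out.append(
            EventSequence(
                pid,
                [DailyEvent(by_date[d]) for d in dates],
                dates,
            )
        )
    return out


def _read_jsonl(stream: IO[str]) -> list[EventSequence]:
    out = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"line {lineno}: invalid JSON") from exc
        try:
            pid = obj["patient_id"]
            raw_events = obj["events"]
        except (TypeError, KeyError) as exc:
            raise FormatError(
                f"line {lineno}: object needs 'patient_id' and 'events'"
            ) from exc
        if not raw_events:
            raise FormatError(f"line {lineno}: patient {pid!r} has no events")
        events, dates = [], []
        for k, ev in enumerate(raw_events, start=1):
            codes = ev.get("codes", [])
            if not codes or any(not c for c in codes):
                raise FormatError(
                    f"line {lineno}: patient {pid!r} event {k} has an empty code field"
                )
            events.append(DailyEvent(codes))
            dates.append(ev.get("date"))
        if all(d is None for d in dates):
            parsed_dates = None
        elif any(d is None for d in dates):
            raise FormatError(f"line {lineno}: patient {pid!r} mixes dated and undated events")
        else:
            parsed_dates = [_parse_date(d, f"line {lineno}") for d in dates]
        out.append(EventSequence(pid, events, parsed_dates))
    return out


def read_sequences(source: IO[str] | str, format: str = "csv") -> list[EventSequence]:
    """Read patient event sequences from a stream or path.

    ``format`` is ``"csv"`` (one code per row; same-day rows merged into
    one daily event) or ``"jsonl"`` (one patient object per line).
    """
    if isinstance(source, (str,)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_sequences(fh, format=format)
    if format == "csv":
        return _read_csv(source)
    if format == "jsonl":
        return _read_jsonl(source)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")


def _synthetic_dates(n: int) -> list[datetime.date]:
    start = datetime.date(2000, 1, 1)
    return [start + datetime.timedelta(days=i) for i in range(n)]


def write_sequences(
    seqs: Iterable[EventSequence], sink: IO[str] | str, format: str = "csv"
) -> None:
    """Write sequences so that :func:`read_sequences` round-trips them.

    In the delimited dialect, undated sequences are written on a synthetic
    strictly-increasing daily grid (CSV cannot express order without
    dates); multi-code events use an intra-field ``|`` separator.
    """
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            write_sequences(seqs, fh, format=format)
        return
    if format == "csv":
        writer = csv.writer(sink)
        writer.writerow(["patient_id", "date", "code"])
        for seq in seqs:
            dates = seq.dates or _synthetic_dates(len(seq))
            for date, event in zip(dates, seq.events):
                writer.writerow(
                    [seq.patient_id, date.isoformat(), CODE_SEPARATOR.join(sorted(event.codes))]
                )
    elif format == "jsonl":
        for seq in seqs:
            obj = {
                "patient_id": seq.patient_id,
                "events": [
                    {
                        "date": seq.dates[i].isoformat() if seq.dates else None,
                        "codes": sorted(ev.codes),
                    }
                    for i, ev in enumerate(seq.events)
                ],
            }
            sink.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")


def sequences_to_string(seqs: Iterable[EventSequence], format: str = "csv") -> str:
    buf = io.StringIO()
    write_sequences(seqs, buf, format=format)
    return buf.getvalue()
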