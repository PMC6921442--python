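"""Ground-truth (reference) alignments derived from synthesis provenance.

A synthetic record knows exactly where each of its positions came from
(the index map maintained during synthesis), so the "true" alignment
against its seed needs no search:

* **global reference** — every surviving seed position is paired with the
  synthetic position that descends from it; seed positions removed by a
  deletion face a gap.  Updated or switched positions remain positional
  pairs: their content changed, so the pair simply scores as a (partial)
  mismatch through the Jaccard similarity.  This is the baseline an
  optimizing aligner must beat — e.g. a single deletion in a 4-event seed
  gives three matches and one gap, S_n = (3 − 1)/4 = 0.50.

* **local reference** — the longest contiguous run of exact-match pair
  columns inside the global reference (ties broken toward the earliest
  run).  Its coverage and normalized score coincide whenever all its
  pairs are perfect matches, which is why a single deletion in a 5-event
  seed yields C = S_n = 0.40 (a 2-of-5 run on either side of the gap).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_global import Alignment, AlignmentColumn, Role
from .align_local import LocalAlignment, compute_coverage
from .records_io import EventSequence
from .scoring import ScoringScheme, pair_similarity
from .synthesis import SyntheticRecord, replay_operation

__all__ = ["ProvenanceError", "ReferenceAlignment", "reference_global", "reference_local"]

_TOL = 1e-9


class ProvenanceError(ValueError):
    """Raised when a record's provenance does not fit the given seed."""


@dataclass(frozen=True)
class ReferenceAlignment:
    """A provenance-derived baseline alignment and its source record."""

    alignment: Alignment | LocalAlignment
    source: SyntheticRecord


def _validate(seed: EventSequence, record: SyntheticRecord) -> None:
    n, m = len(seed), len(record.sequence)
    mapped = [p for p in record.index_map if p is not None]
    if any(not 1 <= p <= n for p in mapped):
        raise ProvenanceError("index_map points outside the seed sequence")
    if any(a >= b for a, b in zip(mapped, mapped[1:])):
        raise ProvenanceError("index_map must be strictly increasing over mapped positions")
    if len(record.index_map) != m:
        raise ProvenanceError("index_map length differs from the synthetic sequence")
    seq = seed
    for op in record.provenance:
        seq = replay_operation(seq, op)
    if tuple(seq.events) != tuple(record.sequence.events):
        raise ProvenanceError("replaying provenance on the seed does not reproduce the record")


def reference_global(
    seed: EventSequence,
    record: SyntheticRecord,
    scheme: ScoringScheme = ScoringScheme(),
) -> ReferenceAlignment:
    """Build the ground-truth global alignment of ``record`` to ``seed``."""
    _validate(seed, record)
    n = len(seed)
    cols: list[AlignmentColumn] = []
    i = 1  # next seed position awaiting a column
    for j, origin in enumerate(record.index_map, start=1):
        if origin is not None:
            while i < origin:  # seed positions deleted before this pair
                cols.append(AlignmentColumn(i, None, Role.GAP_IN_SYNTH, scheme.gap_penalty))
                i += 1
            cols.append(
                AlignmentColumn(
                    origin, j, Role.PAIR,
                    pair_similarity(seed[origin - 1], record.sequence[j - 1], scheme),
                )
            )
            i = origin + 1
        else:  # synthetic position with no seed origin
            cols.append(AlignmentColumn(None, j, Role.GAP_IN_SEED, scheme.gap_penalty))
    while i <= n:  # trailing deletions
        cols.append(AlignmentColumn(i, None, Role.GAP_IN_SYNTH, scheme.gap_penalty))
        i += 1
    raw = sum(c.column_score for c in cols)
    return ReferenceAlignment(
        Alignment(tuple(cols), raw, raw / n, "ref"), record
    )


def reference_local(
    seed: EventSequence,
    record: SyntheticRecord,
    scheme: ScoringScheme = ScoringScheme(),
    min_pair_score: float | None = None,
) -> ReferenceAlignment:
    """Extract the baseline local alignment from the global reference.

    The baseline is the longest contiguous run of pair columns scoring at
    least ``min_pair_score`` (default: the scheme's match score, i.e.
    exact matches only); among equal-length runs the earliest wins.
    ``min_pair_score`` can be lowered to let partial-overlap pairs extend
    a run when events share only some codes.
    """
    ref = reference_global(seed, record, scheme)
    threshold = scheme.match_score if min_pair_score is None else min_pair_score
    cols = ref.alignment.columns

    best: tuple[int, int] | None = None  # (start, stop) half-open over cols
    start = None
    for k, col in enumerate(list(cols) + [None]):  # sentinel flushes last run
        ok = (
            col is not None
            and col.role is Role.PAIR
            and col.column_score >= threshold - _TOL
        )
        if ok and start is None:
            start = k
        elif not ok and start is not None:
            if best is None or k - start > best[1] - best[0]:
                best = (start, k)
            start = None

    n = len(seed)
    if best is None:
        local = LocalAlignment((), 0.0, 0.0, 0.0, None, None, "ref")
    else:
        run = cols[best[0] : best[1]]
        raw = sum(c.column_score for c in run)
        seed_idx = [c.seed_index for c in run]
        synth_idx = [c.synth_index for c in run]
        local = LocalAlignment(
            tuple(run),
            raw,
            raw / n,
            compute_coverage(run, n),
            (min(seed_idx), max(seed_idx)),
            (min(synth_idx), max(synth_idx)),
            "ref",
        )
    return ReferenceAlignment(local, record)
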