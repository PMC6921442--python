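"""Local aligners: Smith-Waterman (SWA) and time warping for local
alignment (DTWL).

Both zero-floor the accumulated score matrix — a cell whose best
accumulated score would be negative is set to 0, masking mismatched
context so that locally similar stretches stand out — and trace back from
the highest-scoring cell until a zero cell is encountered.  The zero cell
terminates the path and is not part of the alignment.

SWA uses gap moves scored by the gap penalty; DTWL replaces gaps with
warp moves scored by the penalized repeat similarity (J - 1), exactly as
the global DTW recurrence does:

    A[i,j] = max( s_pair(Xi,Yj) + A[i-1,j-1],
                  s_warp(Xi,Yj) + A[i-1,j],
                  s_warp(Xi,Yj) + A[i,j-1],
                  0 )                               (DTWL)

Two local quantities are reported against the *seed* sequence of length
N: the normalized score S_n = raw / N, and the coverage C — the fraction
of the seed spanned by the alignment.  Coverage counts the contiguous
span of seed indices touched by the alignment (seed events sitting inside
the span but aligned to gap columns still count: an alignment reaching
from the first to the last seed event has full coverage even if it
bridges a deletion with one gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_global import (
    _DIAG,
    _HORIZ,
    _NONE,
    _VERT,
    AccumulatedMatrix,
    AlignmentColumn,
    Role,
    _check_nonempty,
    _pairwise_scores,
)
from .records_io import EventSequence
from .scoring import ScoringScheme, pair_similarity, warp_similarity

__all__ = ["LocalAlignment", "swa_align", "dtwl_align", "compute_coverage"]


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment with coverage of the seed sequence.

    ``seed_span`` / ``synth_span`` are inclusive 1-based index intervals,
    or ``None`` for an empty alignment (sequences sharing nothing).
    """

    columns: tuple[AlignmentColumn, ...]
    raw_score: float
    normalized_score: float
    coverage: float
    seed_span: tuple[int, int] | None
    synth_span: tuple[int, int] | None
    algorithm: str


def compute_coverage(columns, seed_length: int) -> float:
    """Fraction of the seed sequence spanned by the alignment columns.

    Span-based: (max seed index − min seed index + 1) / seed_length over
    columns carrying a seed index; 0 for an empty alignment.
    """
    touched = [c.seed_index for c in columns if c.seed_index is not None]
    if not touched:
        return 0.0
    return (max(touched) - min(touched) + 1) / seed_length


def _span(indices: list[int]) -> tuple[int, int] | None:
    return (min(indices), max(indices)) if indices else None


def _local_matrix(
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme,
    warped: bool,
) -> AccumulatedMatrix:
    _check_nonempty(seed, synth)
    n, m = len(seed), len(synth)
    gp = scheme.gap_penalty
    sp = _pairwise_scores(seed, synth, pair_similarity, scheme)
    sw = _pairwise_scores(seed, synth, warp_similarity, scheme) if warped else None
    A = np.zeros((n + 1, m + 1))
    moves = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if warped:
                vert = sw[i - 1, j - 1] + A[i - 1, j]
                horiz = sw[i - 1, j - 1] + A[i, j - 1]
            else:
                vert = A[i - 1, j] + gp
                horiz = A[i, j - 1] + gp
            best, move = sp[i - 1, j - 1] + A[i - 1, j - 1], _DIAG
            if vert > best:
                best, move = vert, _VERT
            if horiz > best:
                best, move = horiz, _HORIZ
            if best <= 0.0:  # zero floor masks negative context
                best, move = 0.0, _NONE
            A[i, j] = best
            moves[i, j] = move
    return AccumulatedMatrix(A, moves)


def _traceback_start(A: np.ndarray, tiebreak: str) -> tuple[int, int]:
    """Cell holding the matrix maximum; ties resolved in row-major order."""
    flat = np.flatnonzero(A == A.max())
    idx = flat[0] if tiebreak == "first" else flat[-1]
    i, j = np.unravel_index(idx, A.shape)
    return int(i), int(j)


def _local_align(
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme,
    warped: bool,
    algorithm: str,
    tiebreak: str,
) -> LocalAlignment:
    if tiebreak not in ("first", "last"):
        raise ValueError("tiebreak must be 'first' or 'last'")
    matrix = _local_matrix(seed, synth, scheme, warped)
    A, moves = matrix.scores, matrix.moves
    raw = float(A.max())
    n_seed = len(seed)
    if raw <= 0.0:  # nothing aligns: the empty local alignment
        return LocalAlignment((), 0.0, 0.0, 0.0, None, None, algorithm)
    i, j = _traceback_start(A, tiebreak)
    cols: list[AlignmentColumn] = []
    while A[i, j] > 0.0:
        move = moves[i, j]
        if move == _DIAG:
            cols.append(
                AlignmentColumn(i, j, Role.PAIR, pair_similarity(seed[i - 1], synth[j - 1], scheme))
            )
            i, j = i - 1, j - 1
        elif move == _VERT:
            if warped:
                cols.append(
                    AlignmentColumn(
                        i, j, Role.WARP_REPEAT_SYNTH,
                        warp_similarity(seed[i - 1], synth[j - 1], scheme),
                    )
                )
            else:
                cols.append(AlignmentColumn(i, None, Role.GAP_IN_SYNTH, scheme.gap_penalty))
            i -= 1
        else:  # _HORIZ; _NONE is impossible while A > 0
            if warped:
                cols.append(
                    AlignmentColumn(
                        i, j, Role.WARP_REPEAT_SEED,
                        warp_similarity(seed[i - 1], synth[j - 1], scheme),
                    )
                )
            else:
                cols.append(AlignmentColumn(None, j, Role.GAP_IN_SEED, scheme.gap_penalty))
            j -= 1
    cols.reverse()
    seed_idx = [c.seed_index for c in cols if c.seed_index is not None]
    synth_idx = [c.synth_index for c in cols if c.synth_index is not None]
    return LocalAlignment(
        tuple(cols),
        raw,
        raw / n_seed,
        compute_coverage(cols, n_seed),
        _span(seed_idx),
        _span(synth_idx),
        algorithm,
    )


def swa_align(
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme = ScoringScheme(),
    tiebreak: str = "last",
) -> LocalAlignment:
    """Locally align two sequences with Smith-Waterman."""
    return _local_align(seed, synth, scheme, warped=False, algorithm="swa", tiebreak=tiebreak)


def dtwl_align(
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme = ScoringScheme(),
    tiebreak: str = "last",
) -> LocalAlignment:
    """Locally align two sequences with zero-floored time warping."""
    return _local_align(seed, synth, scheme, warped=True, algorithm="dtwl", tiebreak=tiebreak)
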