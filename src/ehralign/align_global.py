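"""Global aligners for daily-event sequences: time warping (DTW) and
Needleman-Wunsch (NWA).

Both fill an accumulated score matrix A of shape (n+1) x (m+1) for a seed
sequence X (length n) and a synthetic/query sequence Y (length m) and
trace back from A[n, m].

DTW recurrence (warping; no gaps):

    A[0,0] = 0;  A[i,0] = A[0,j] = -inf  (forces first-index matching)
    A[i,j] = max( s_pair(Xi,Yj) + A[i-1,j-1],      # diagonal: new pair
                  s_warp(Xi,Yj) + A[i-1,j],        # vertical: Yj repeated
                  s_warp(Xi,Yj) + A[i,j-1] )       # horizontal: Xi repeated

where the diagonal move scores the pair similarity 2J-1 and the
non-diagonal (warp) moves score the penalized repeat similarity J-1: a
1-to-n index match stretches one sequence by repeating an element, and
the repeated pairing is penalized rather than rewarded.  Tracing back
from A[n, m] enforces last-index matching; the -inf borders enforce
first-index matching.

NWA recurrence (gaps; no warping):

    A[0,0] = 0;  A[i,0] = i*gp;  A[0,j] = j*gp
    A[i,j] = max( A[i-1,j-1] + s_pair(Xi,Yj),
                  A[i-1,j] + gp,                    # Yj faces a gap
                  A[i,j-1] + gp )                   # Xi faces a gap

Traceback ties are broken diagonal > vertical > horizontal so output is
deterministic; co-optimal paths exist and any fixed order yields the same
(raw and normalized) score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np

from .records_io import DailyEvent, EventSequence
from .scoring import ScoringScheme, pair_similarity, warp_similarity

__all__ = [
    "Role",
    "AlignmentColumn",
    "AccumulatedMatrix",
    "Alignment",
    "dtw_align",
    "nwa_align",
    "brute_force_best_alignment",
]

# move codes stored in the traceback grid
_NONE, _DIAG, _VERT, _HORIZ = 0, 1, 2, 3


class Role(str, Enum):
    """What an alignment column represents."""

    PAIR = "pair"                          # Xi aligned to Yj
    GAP_IN_SEED = "gap_in_seed"            # Yj faces a gap (seed side empty)
    GAP_IN_SYNTH = "gap_in_synth"          # Xi faces a gap (synth side empty)
    WARP_REPEAT_SEED = "warp_repeat_seed"  # Xi repeated: seed stretched
    WARP_REPEAT_SYNTH = "warp_repeat_synth"  # Yj repeated: synth stretched


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of an alignment: (seed position, synth position, role, score).

    Positions are 1-based; a gap role leaves exactly one side ``None``; a
    warp role repeats an index already emitted on that side.
    """

    seed_index: int | None
    synth_index: int | None
    role: Role
    column_score: float


@dataclass(frozen=True)
class AccumulatedMatrix:
    """A filled DP grid: accumulated scores plus the traceback moves."""

    scores: np.ndarray  # (n+1, m+1) float
    moves: np.ndarray   # (n+1, m+1) int8 in {none, diag, vert, horiz}


@dataclass(frozen=True)
class Alignment:
    """A global alignment: ordered columns plus raw and normalized scores.

    ``normalized_score`` (S_n) is the raw score divided by the number of
    daily events in the *seed* sequence, so scores of synthetic variants
    of one seed are comparable.
    """

    columns: tuple[AlignmentColumn, ...]
    raw_score: float
    normalized_score: float
    algorithm: str


def _pairwise_scores(
    seed: EventSequence,
    synth: EventSequence,
    fn: Callable[[DailyEvent, DailyEvent, ScoringScheme], float],
    scheme: ScoringScheme,
) -> np.ndarray:
    n, m = len(seed), len(synth)
    s = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s[i, j] = fn(seed[i], synth[j], scheme)
    return s


def _argmax3(diag: float, vert: float, horiz: float) -> tuple[float, int]:
    """Max of three candidates with tie order diagonal > vertical > horizontal."""
    best, move = diag, _DIAG
    if vert > best:
        best, move = vert, _VERT
    if horiz > best:
        best, move = horiz, _HORIZ
    return best, move


def _check_nonempty(seed: EventSequence, synth: EventSequence) -> None:
    # EventSequence already guarantees >= 1 event; guard against raw lists
    if len(seed) == 0 or len(synth) == 0:
        raise ValueError("cannot align empty sequences")


def dtw_matrix(
    seed: EventSequence, synth: EventSequence, scheme: ScoringScheme = ScoringScheme()
) -> AccumulatedMatrix:
    """Fill the DTW accumulated score matrix (with traceback moves)."""
    _check_nonempty(seed, synth)
    n, m = len(seed), len(synth)
    sp = _pairwise_scores(seed, synth, pair_similarity, scheme)
    sw = _pairwise_scores(seed, synth, warp_similarity, scheme)
    A = np.full((n + 1, m + 1), -np.inf)
    moves = np.zeros((n + 1, m + 1), dtype=np.int8)
    A[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            A[i, j], moves[i, j] = _argmax3(
                sp[i - 1, j - 1] + A[i - 1, j - 1],
                sw[i - 1, j - 1] + A[i - 1, j],
                sw[i - 1, j - 1] + A[i, j - 1],
            )
    return AccumulatedMatrix(A, moves)


def nwa_matrix(
    seed: EventSequence, synth: EventSequence, scheme: ScoringScheme = ScoringScheme()
) -> AccumulatedMatrix:
    """Fill the Needleman-Wunsch accumulated score matrix."""
    _check_nonempty(seed, synth)
    n, m = len(seed), len(synth)
    gp = scheme.gap_penalty
    sp = _pairwise_scores(seed, synth, pair_similarity, scheme)
    A = np.zeros((n + 1, m + 1))
    moves = np.zeros((n + 1, m + 1), dtype=np.int8)
    A[1:, 0] = gp * np.arange(1, n + 1)
    A[0, 1:] = gp * np.arange(1, m + 1)
    moves[1:, 0] = _VERT
    moves[0, 1:] = _HORIZ
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            A[i, j], moves[i, j] = _argmax3(
                A[i - 1, j - 1] + sp[i - 1, j - 1],
                A[i - 1, j] + gp,
                A[i, j - 1] + gp,
            )
    return AccumulatedMatrix(A, moves)


def _traceback_global(
    matrix: AccumulatedMatrix,
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme,
    warped: bool,
) -> list[AlignmentColumn]:
    """Follow stored moves from (n, m) back to (0, 0); emit columns forward."""
    i, j = len(seed), len(synth)
    cols: list[AlignmentColumn] = []
    while i > 0 or j > 0:
        move = matrix.moves[i, j]
        if move == _DIAG:
            cols.append(
                AlignmentColumn(i, j, Role.PAIR, pair_similarity(seed[i - 1], synth[j - 1], scheme))
            )
            i, j = i - 1, j - 1
        elif move == _VERT:
            if warped:  # seed advances, synth element j is repeated
                cols.append(
                    AlignmentColumn(
                        i, j, Role.WARP_REPEAT_SYNTH,
                        warp_similarity(seed[i - 1], synth[j - 1], scheme),
                    )
                )
            else:  # seed event i faces a gap on the synth side
                cols.append(AlignmentColumn(i, None, Role.GAP_IN_SYNTH, scheme.gap_penalty))
            i -= 1
        elif move == _HORIZ:
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
        else:  # pragma: no cover - would indicate a corrupt traceback grid
            raise RuntimeError(f"traceback stuck at cell ({i}, {j})")
    cols.reverse()
    return cols


def dtw_align(
    seed: EventSequence, synth: EventSequence, scheme: ScoringScheme = ScoringScheme()
) -> Alignment:
    """Globally align two sequences by dynamic time warping.

    Every index of each sequence matches one or more indices of the
    other; first and last indices must match; no gaps.  Warp-repeat
    columns (the 1-to-n part of a match) are score-penalized, so S_n = 1
    still characterizes identical sequences.
    """
    matrix = dtw_matrix(seed, synth, scheme)
    cols = _traceback_global(matrix, seed, synth, scheme, warped=True)
    raw = float(matrix.scores[len(seed), len(synth)])
    return Alignment(tuple(cols), raw, raw / len(seed), "dtw")


def nwa_align(
    seed: EventSequence, synth: EventSequence, scheme: ScoringScheme = ScoringScheme()
) -> Alignment:
    """Globally align two sequences with Needleman-Wunsch (gap-based)."""
    matrix = nwa_matrix(seed, synth, scheme)
    cols = _traceback_global(matrix, seed, synth, scheme, warped=False)
    raw = float(matrix.scores[len(seed), len(synth)])
    return Alignment(tuple(cols), raw, raw / len(seed), "nwa")


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive enumeration of legal paths, used in tests to
# certify the DP implementations on small instances.  Deliberately naive.
# ---------------------------------------------------------------------------

_ORACLE_MAX_LEN = 7


def brute_force_best_alignment(
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme = ScoringScheme(),
    mode: str = "dtw",
) -> float:
    """Optimal raw alignment score by exhaustive path enumeration.

    Enumerates every path that is legal under ``mode``'s move and
    boundary rules and returns the maximal total column score.  Runtime
    is exponential; sequences are capped at length 7.  This is a test
    oracle, independent of the DP code paths.
    """
    n, m = len(seed), len(synth)
    if n > _ORACLE_MAX_LEN or m > _ORACLE_MAX_LEN:
        raise ValueError(f"oracle is capped at length {_ORACLE_MAX_LEN} (got {n}, {m})")
    if mode not in ("dtw", "nwa", "swa", "dtwl"):
        raise ValueError(f"unknown mode {mode!r}")

    def sp(i: int, j: int) -> float:
        return pair_similarity(seed[i - 1], synth[j - 1], scheme)

    def sw(i: int, j: int) -> float:
        return warp_similarity(seed[i - 1], synth[j - 1], scheme)

    gp = scheme.gap_penalty

    if mode == "dtw":
        # paths of (move, cell) from (1,1) to (n,m); first cell entered diagonally
        def best_from(i: int, j: int) -> float:
            if i == n and j == m:
                return 0.0
            cands = []
            if i < n and j < m:
                cands.append(sp(i + 1, j + 1) + best_from(i + 1, j + 1))
            if i < n:
                cands.append(sw(i + 1, j) + best_from(i + 1, j))
            if j < m:
                cands.append(sw(i, j + 1) + best_from(i, j + 1))
            return max(cands)

        return sp(1, 1) + best_from(1, 1)

    if mode == "nwa":
        def best_from(i: int, j: int) -> float:
            if i == n and j == m:
                return 0.0
            cands = []
            if i < n and j < m:
                cands.append(sp(i + 1, j + 1) + best_from(i + 1, j + 1))
            if i < n:
                cands.append(gp + best_from(i + 1, j))
            if j < m:
                cands.append(gp + best_from(i, j + 1))
            return max(cands)

        return best_from(0, 0)

    # local modes: a path may start and stop at any cell; column scores depend
    # on the arrival move (pair for diagonal; gap or warp otherwise).  The
    # best local score is the max over all subpaths, floored at 0 (the empty
    # alignment is always available).
    def nondiag(i: int, j: int) -> float:
        return sw(i, j) if mode == "dtwl" else gp

    def best_suffix(i: int, j: int) -> float:
        """Best total over all (possibly empty) continuations from cell (i, j)."""
        best = 0.0  # stop here
        if i < n and j < m:
            best = max(best, sp(i + 1, j + 1) + best_suffix(i + 1, j + 1))
        if i < n:
            best = max(best, nondiag(i + 1, j) + best_suffix(i + 1, j))
        if j < m:
            best = max(best, nondiag(i, j + 1) + best_suffix(i, j + 1))
        return best

    best = 0.0
    for i, j in itertools.product(range(1, n + 1), range(1, m + 1)):
        # first column of a local path may be entered by any move type
        best = max(best, sp(i, j) + best_suffix(i, j))
        best = max(best, nondiag(i, j) + best_suffix(i, j))
    return best
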