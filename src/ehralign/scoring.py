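"""Similarity scoring for set-valued daily events.

The scoring system rewards a matching pair of daily events with +1 and
penalizes a mismatch or a gap with -1, like the simplest substitution
schemes used for biological sequences.  Because a daily event is a *set*
of diagnosis codes rather than a single letter, partial overlap is graded
with the Jaccard index J = |X ∩ Y| / |X ∪ Y|:

* an aligned pair of events scores ``s(X, Y) = 2·J(X, Y) − 1``
  (match = +1, total mismatch = −1);
* an event paired against a *warp-inserted* copy of its neighbour (the
  repeat columns produced by time-warping aligners) scores
  ``s(X, Y) = J(X, Y) − 1``, i.e. at best 0 — repeating an element never
  earns a reward, it is only penalized less when the repeat fits.

Both formulas generalize to a configurable (match, mismatch, gap) triple;
the defaults are the published 1 / −1 / −1 system and all worked numbers
in the documentation assume them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .records_io import DailyEvent

__all__ = ["ScoringScheme", "jaccard", "pair_similarity", "warp_similarity"]


@dataclass(frozen=True)
class ScoringScheme:
    """Match / mismatch / gap parameters of the scoring system."""

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_penalty: float = -1.0

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")


def _as_set(x: DailyEvent | Iterable[str]) -> frozenset[str]:
    if isinstance(x, DailyEvent):
        return x.codes
    s = frozenset(x)
    if not s:
        raise ValueError("daily events are never empty: cannot score an empty code set")
    return s


def jaccard(a: DailyEvent | Iterable[str], b: DailyEvent | Iterable[str]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two non-empty code sets."""
    sa, sb = _as_set(a), _as_set(b)
    return len(sa & sb) / len(sa | sb)


def pair_similarity(
    x: DailyEvent | Iterable[str],
    y: DailyEvent | Iterable[str],
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Similarity of two aligned daily events.

    Linearly interpolates between ``mismatch_score`` (disjoint sets) and
    ``match_score`` (identical sets); with the default scheme this is
    ``2·J − 1``.
    """
    j = jaccard(x, y)
    return scheme.mismatch_score + (scheme.match_score - scheme.mismatch_score) * j


def warp_similarity(
    x: DailyEvent | Iterable[str],
    y: DailyEvent | Iterable[str],
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Similarity of an original event against a warp-inserted repeat.

    Ranges from ``mismatch_score`` (disjoint) to 0 (identical); with the
    default scheme this is ``J − 1``.  The zero ceiling means stretching a
    sequence is never rewarded, only tolerated.
    """
    j = jaccard(x, y)
    return scheme.mismatch_score * (1.0 - j)
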