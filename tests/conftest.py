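"""Shared helpers: compact sequence builders, random sequence generators,
and an alignment-legality validator used across test modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ehralign import (
    Alignment,
    DailyEvent,
    EventSequence,
    LocalAlignment,
    Role,
    ScoringScheme,
    pair_similarity,
    warp_similarity,
)


def seq(letters: str, pid: str = "p") -> EventSequence:
    """One single-code daily event per character: seq("abbc")."""
    return EventSequence(pid, [DailyEvent({c}) for c in letters])


def mseq(events: list[set[str]], pid: str = "p") -> EventSequence:
    """Multi-code events from a list of sets."""
    return EventSequence(pid, [DailyEvent(e) for e in events])


def random_sequence(
    rng: np.random.Generator,
    max_len: int = 6,
    alphabet: str = "abc",
    multi_code: bool = False,
    min_len: int = 1,
) -> EventSequence:
    n = int(rng.integers(min_len, max_len + 1))
    events = []
    for _ in range(n):
        k = int(rng.integers(1, 3)) if multi_code else 1
        codes = set(rng.choice(list(alphabet), size=k, replace=False))
        events.append(DailyEvent(codes))
    return EventSequence("r", events)


def assert_legal_alignment(
    aln: Alignment | LocalAlignment,
    seed: EventSequence,
    synth: EventSequence,
    scheme: ScoringScheme = ScoringScheme(),
    global_: bool = True,
) -> None:
    """Structural invariants every emitted alignment must satisfy."""
    # per-column score correctness and null-index discipline
    for c in aln.columns:
        if c.role is Role.PAIR:
            assert c.seed_index is not None and c.synth_index is not None
            expect = pair_similarity(seed[c.seed_index - 1], synth[c.synth_index - 1], scheme)
        elif c.role in (Role.WARP_REPEAT_SEED, Role.WARP_REPEAT_SYNTH):
            assert c.seed_index is not None and c.synth_index is not None
            expect = warp_similarity(seed[c.seed_index - 1], synth[c.synth_index - 1], scheme)
        elif c.role is Role.GAP_IN_SYNTH:
            assert c.seed_index is not None and c.synth_index is None
            expect = scheme.gap_penalty
        else:  # GAP_IN_SEED
            assert c.seed_index is None and c.synth_index is not None
            expect = scheme.gap_penalty
        assert math.isclose(c.column_score, expect, abs_tol=1e-12)

    # column scores sum to the reported raw score
    assert math.isclose(sum(c.column_score for c in aln.columns), aln.raw_score, abs_tol=1e-9)

    for side, n_total in (("seed", len(seed)), ("synth", len(synth))):
        idx = [getattr(c, f"{side}_index") for c in aln.columns]
        idx = [i for i in idx if i is not None]
        assert idx == sorted(idx), f"{side} indices must be monotone"
        covered = sorted(set(idx))
        if global_:
            assert covered == list(range(1, n_total + 1)), f"{side} must be fully covered"
        elif covered:
            lo, hi = covered[0], covered[-1]
            assert covered == list(range(lo, hi + 1)), f"{side} coverage must be contiguous"
        # warp repeats aside, each index is consumed exactly once
        repeat_role = Role.WARP_REPEAT_SEED if side == "seed" else Role.WARP_REPEAT_SYNTH
        fresh = [
            getattr(c, f"{side}_index")
            for c in aln.columns
            if c.role is not repeat_role and getattr(c, f"{side}_index") is not None
        ]
        assert len(fresh) == len(set(fresh)), f"{side} index consumed twice outside a warp"


@pytest.fixture
def scheme() -> ScoringScheme:
    return ScoringScheme()
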