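"""Provenance-derived reference alignments, global and local."""

import numpy as np
import pytest

from ehralign import (
    Operation,
    ProvenanceError,
    SyntheticRecord,
    default_vocabulary,
    dtwl_align,
    generate_seed_sequence,
    nwa_align,
    reference_global,
    reference_local,
    replay_operation,
    swa_align,
    synthesize_benchmark,
)

from conftest import seq

VOCAB = default_vocabulary(20)


def record_from(seed, *ops):
    """Build a SyntheticRecord by replaying ops and tracking the index map."""
    s = seed
    index_map = list(range(1, len(seed) + 1))
    for op in ops:
        s = replay_operation(s, op)
        if op.kind == "delete":
            if op.level == "daily":
                (p,) = op.positions
                del index_map[p - 1]
            else:
                ((a, b),) = op.positions
                del index_map[a - 1 : b]
    return SyntheticRecord(s, tuple(ops), tuple(index_map))


class TestGlobalReference:
    def test_deletion_becomes_gap(self):
        """Delete position 3 of a 4-event seed: 3 matches + 1 gap = 0.50."""
        rec = record_from(seq("abbc"), Operation("delete", "daily", (3,)))
        ref = reference_global(seq("abbc"), rec).alignment
        assert ref.normalized_score == pytest.approx(0.50)
        roles = [c.role.value for c in ref.columns]
        assert roles == ["pair", "pair", "gap_in_synth", "pair"]

    def test_adjacent_switch_scores_zero(self):
        """Switched events stay positional pairs and score as mismatches:
        (1 - 1 - 1 + 1)/4 = 0."""
        rec = record_from(seq("abcd"), Operation("switch", "daily", (2, 3)))
        ref = reference_global(seq("abcd"), rec).alignment
        assert ref.normalized_score == pytest.approx(0.0)

    def test_update_is_a_positional_mismatch(self):
        rec = record_from(
            seq("abbc"),
            Operation("update", "daily", (3,), {"action": "replace", "old_code": "b", "new_code": "z"}),
        )
        ref = reference_global(seq("abbc"), rec).alignment
        assert ref.normalized_score == pytest.approx(0.50)

    def test_identity_record_scores_one(self):
        s = seq("abcde")
        rec = record_from(s)
        assert reference_global(s, rec).alignment.normalized_score == pytest.approx(1.0)

    def test_delete_only_closed_form(self):
        """With d deletions from an all-distinct seed, raw = (N-d) - d."""
        rng = np.random.default_rng(41)
        for _ in range(20):
            seed = generate_seed_sequence(int(rng.integers(6, 20)), VOCAB, rng=int(rng.integers(1e6)))
            (rec,) = synthesize_benchmark(seed, ["x x"], rng=int(rng.integers(1e6)), vocab=VOCAB)
            n, d = len(seed), 2
            ref = reference_global(seed, rec).alignment
            assert ref.raw_score == pytest.approx(n - 2 * d)
            assert ref.normalized_score == pytest.approx((n - 2 * d) / n)

    def test_inconsistent_provenance_rejected(self):
        rec = record_from(seq("abbc"), Operation("delete", "daily", (3,)))
        tampered = SyntheticRecord(seq("azc"), rec.provenance, rec.index_map)
        with pytest.raises(ProvenanceError):
            reference_global(seq("abbc"), tampered)


class TestLocalReference:
    def test_longest_exact_run_after_deletion_len5(self):
        """Deleting the middle of three repeats leaves two 2-long exact
        runs; earliest wins: C = S_n = 0.40."""
        rec = record_from(seq("abbbc"), Operation("delete", "daily", (3,)))
        ref = reference_local(seq("abbbc"), rec).alignment
        assert ref.coverage == pytest.approx(0.40)
        assert ref.normalized_score == pytest.approx(0.40)
        assert ref.seed_span == (1, 2)  # earliest of the tied runs

    def test_longest_exact_run_after_deletion_len4(self):
        rec = record_from(seq("abbc"), Operation("delete", "daily", (3,)))
        ref = reference_local(seq("abbc"), rec).alignment
        assert ref.coverage == pytest.approx(0.50)
        assert ref.normalized_score == pytest.approx(0.50)
        assert ref.seed_span == (1, 2)

    def test_identity_record_full_run(self):
        s = seq("abcde")
        ref = reference_local(s, record_from(s)).alignment
        assert ref.coverage == pytest.approx(1.0)
        assert ref.normalized_score == pytest.approx(1.0)

    def test_no_exact_match_yields_empty_reference(self):
        s = seq("ab")
        rec = record_from(
            s,
            Operation("update", "daily", (1,), {"action": "replace", "old_code": "a", "new_code": "x"}),
            Operation("update", "daily", (2,), {"action": "replace", "old_code": "b", "new_code": "y"}),
        )
        ref = reference_local(s, rec).alignment
        assert ref.raw_score == 0.0 and ref.coverage == 0.0

    def test_threshold_can_admit_partial_overlap_pairs(self):
        from ehralign import DailyEvent, EventSequence

        seed = EventSequence("p", [DailyEvent({"a", "b"}), DailyEvent({"c"})])
        rec = record_from(
            seed,
            Operation("update", "daily", (1,), {"action": "remove", "old_code": "b"}),
        )
        strict = reference_local(seed, rec).alignment
        lax = reference_local(seed, rec, min_pair_score=0.0).alignment
        assert strict.seed_span == (2, 2)
        assert lax.seed_span == (1, 2)  # the J=1/2 pair now extends the run


class TestDominanceOverReference:
    def test_aligners_never_fall_below_their_reference(self):
        """The reference path is feasible for NWA; its exact-match run is
        feasible for both locals."""
        rng = np.random.default_rng(43)
        for trial in range(30):
            seed = generate_seed_sequence(12, VOCAB, rng=trial)
            records = synthesize_benchmark(
                seed, ["x", "u", "s", "x s", "X", "S"], rng=trial + 100, vocab=VOCAB
            )
            for rec in records:
                ref_g = reference_global(seed, rec).alignment
                ref_l = reference_local(seed, rec).alignment
                assert nwa_align(seed, rec.sequence).raw_score >= ref_g.raw_score - 1e-9
                assert swa_align(seed, rec.sequence).raw_score >= ref_l.raw_score - 1e-9
                assert dtwl_align(seed, rec.sequence).raw_score >= ref_l.raw_score - 1e-9
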