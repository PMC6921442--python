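"""Synthesis: block sizing, mutation semantics, provenance replay, and
seed-sequence generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehralign import (
    DEFAULT_DESIGN,
    DailyEvent,
    EventSequence,
    Operation,
    SequenceProfile,
    apply_operation,
    block_size,
    default_vocabulary,
    generate_seed_sequence,
    replay_operation,
    synthesize_benchmark,
)

from conftest import seq

VOCAB = default_vocabulary(20)


class TestBlockSize:
    @pytest.mark.parametrize("n,expected", [(9, 2), (84, 8), (224, 22), (458, 45)])
    def test_seed_patient_block_sizes(self, n, expected):
        assert block_size(n) == expected

    def test_floor_and_minimum(self):
        assert block_size(1) == 2  # min applies below n=20
        assert block_size(19) == 2
        assert block_size(20) == 2
        assert block_size(29) == 2
        assert block_size(30) == 3


class TestDailyOperations:
    def test_delete_removes_chosen_event(self):
        s = seq("abbc")
        out, op = apply_operation(s, "delete", "daily", rng=0, vocab=VOCAB)
        assert len(out) == 3
        (p,) = op.positions
        assert list(out.events) == list(s.events[: p - 1]) + list(s.events[p:])

    def test_switch_swaps_code_sets(self):
        s = seq("abcd")
        out, op = apply_operation(s, "switch", "daily", rng=1, vocab=VOCAB)
        p, q = op.positions
        assert out.events[p - 1] == s.events[q - 1]
        assert out.events[q - 1] == s.events[p - 1]
        assert len(out) == 4

    def test_switch_twice_restores(self):
        s = seq("abcd")
        out, op = apply_operation(s, "switch", "daily", rng=2, vocab=VOCAB)
        again = replay_operation(out, op)
        assert tuple(again.events) == tuple(s.events)

    def test_update_single_code_event_forces_replacement(self):
        s = seq("a")
        for trial in range(20):  # removal branch must never trigger
            out, op = apply_operation(s, "update", "daily", rng=trial, vocab=VOCAB)
            assert op.details["action"] == "replace"
            assert len(out.events[0]) == 1
            assert op.details["new_code"] not in s.events[0]

    def test_update_multi_code_event_either_branch(self):
        s = EventSequence("p", [DailyEvent({"a", "b", "c"})])
        seen = set()
        for trial in range(30):
            out, op = apply_operation(s, "update", "daily", rng=trial, vocab=VOCAB)
            seen.add(op.details["action"])
            if op.details["action"] == "remove":
                assert len(out.events[0]) == 2
            else:
                assert len(out.events[0]) == 3
        assert seen == {"replace", "remove"}

    def test_delete_needs_two_events(self):
        with pytest.raises(ValueError):
            apply_operation(seq("a"), "delete", "daily", rng=0, vocab=VOCAB)


class TestBlockOperations:
    def test_block_delete_removes_block_size_events(self):
        s = seq("abcdefghijkl" * 3)  # n=36, block=3
        out, op = apply_operation(s, "delete", "block", rng=0, vocab=VOCAB)
        assert len(out) == 33
        ((a, b),) = op.positions
        assert b - a + 1 == 3

    def test_block_update_preserves_length(self):
        s = seq("abcdefghij")
        out, op = apply_operation(s, "update", "block", rng=0, vocab=VOCAB)
        assert len(out) == len(s)
        ((a, b),) = op.positions
        assert len(op.details["replacement"]) == b - a + 1

    def test_block_switch_swaps_disjoint_equal_blocks(self):
        s = seq("abcdefghij")
        out, op = apply_operation(s, "switch", "block", rng=0, vocab=VOCAB)
        (a1, b1), (a2, b2) = op.positions
        assert b1 < a2 and (b1 - a1) == (b2 - a2)
        assert out.events[a1 - 1 : b1] == s.events[a2 - 1 : b2]
        assert len(out) == len(s)

    def test_block_switch_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="4"):
            apply_operation(seq("abc"), "switch", "block", rng=0, vocab=VOCAB)


class TestBenchmarkSynthesis:
    def test_default_design_has_20_rows(self):
        seed = generate_seed_sequence(30, VOCAB, rng=0)
        records = synthesize_benchmark(seed, rng=1, vocab=VOCAB)
        assert len(records) == len(DEFAULT_DESIGN) == 20

    def test_row_labels_map_to_operations(self):
        seed = generate_seed_sequence(30, VOCAB, rng=0)
        records = synthesize_benchmark(seed, ["x x", "X U S"], rng=1, vocab=VOCAB)
        assert [op.kind for op in records[0].provenance] == ["delete", "delete"]
        assert all(op.level == "daily" for op in records[0].provenance)
        assert [op.kind for op in records[1].provenance] == ["delete", "update", "switch"]
        assert all(op.level == "block" for op in records[1].provenance)

    def test_empty_design_gives_empty_list(self):
        seed = generate_seed_sequence(10, VOCAB, rng=0)
        assert synthesize_benchmark(seed, [], rng=0, vocab=VOCAB) == []

    def test_unknown_label_rejected(self):
        seed = generate_seed_sequence(10, VOCAB, rng=0)
        with pytest.raises(ValueError, match="label"):
            synthesize_benchmark(seed, ["q"], rng=0, vocab=VOCAB)

    def test_reproducible_given_seed(self):
        seed = generate_seed_sequence(25, VOCAB, rng=5)
        a = synthesize_benchmark(seed, rng=42, vocab=VOCAB)
        b = synthesize_benchmark(seed, rng=42, vocab=VOCAB)
        assert [r.sequence.events for r in a] == [r.sequence.events for r in b]
        assert [r.provenance for r in a] == [r.provenance for r in b]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.sampled_from(DEFAULT_DESIGN))
    def test_provenance_replays_bit_identical(self, rng_seed, label):
        """Replaying the recorded operations on the seed reproduces the
        synthetic sequence exactly (the index-map's ground truth)."""
        seed = generate_seed_sequence(24, VOCAB, rng=rng_seed)
        (record,) = synthesize_benchmark(seed, [label], rng=rng_seed + 1, vocab=VOCAB)
        replayed = seed
        for op in record.provenance:
            replayed = replay_operation(replayed, op)
        assert tuple(replayed.events) == tuple(record.sequence.events)
        # deletions shrink, updates/switches preserve length
        n_del = sum(
            (op.positions[0][1] - op.positions[0][0] + 1) if op.level == "block" else 1
            for op in record.provenance
            if op.kind == "delete"
        )
        assert len(record.sequence) == len(seed) - n_del
        mapped = [p for p in record.index_map if p is not None]
        assert mapped == sorted(set(mapped))

    def test_operation_json_round_trip(self):
        seed = generate_seed_sequence(30, VOCAB, rng=0)
        (record,) = synthesize_benchmark(seed, ["X U S"], rng=3, vocab=VOCAB)
        for op in record.provenance:
            assert Operation.from_json(op.to_json()) == op


class TestSeedGeneration:
    def test_postconditions_small_sequence(self):
        s = generate_seed_sequence(9, VOCAB, rng=0)
        assert len(s) == 9
        assert any(len(ev) > 1 for ev in s.events)  # a multi-diagnosis day
        counts = {}
        for ev in s.events:
            for c in ev.codes:
                counts[c] = counts.get(c, 0) + 1
        assert max(counts.values()) >= 2  # a chronic-style recurring code
        assert min(counts.values()) == 1  # an acute-style isolated code

    def test_deterministic(self):
        a = generate_seed_sequence(84, rng=9)
        b = generate_seed_sequence(84, rng=9)
        assert a.events == b.events

    def test_codes_drawn_from_vocabulary(self):
        vocab = default_vocabulary(582)
        s = generate_seed_sequence(84, vocab, rng=1)
        used = {c for ev in s.events for c in ev.codes}
        assert used <= set(vocab)

    def test_impossible_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_seed_sequence(5, VOCAB, SequenceProfile(chronic_days=9), rng=0)

    def test_small_vocab_rejected(self):
        with pytest.raises(ValueError):
            generate_seed_sequence(5, ("a", "b", "c"), rng=0)

    def test_dates_strictly_increasing(self):
        s = generate_seed_sequence(12, VOCAB, rng=2)
        assert s.dates is not None
        assert all(a < b for a, b in zip(s.dates, s.dates[1:]))
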