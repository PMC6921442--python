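# Methods

## Sequence model

A patient record is an ordered sequence **X** = [X₁, …, Xₙ] of daily
events, each Xᵢ a non-empty set of diagnosis-code strings (every code
recorded on one calendar date, across all visits that day). Alignment
consumes only the *order* of daily events; inter-event time gaps are
deliberately ignored (a long silence in a record is ambiguous between
"healthy" and "unobserved", so the aligners make no use of it). Dates are
carried for serialization and provenance only.

Same-day records are merged by code-set union when reading delimited
input, because the daily event — not the visit — is the alignment symbol;
duplicate codes collapse under set semantics, the only reading compatible
with Jaccard scoring. Code grouping (truncating at the first period,
`195.1 → 195`) is exposed as an explicit preprocessing function and never
applied implicitly; mapping tables between coding systems are out of
scope.

## Scoring

For daily events X, Y with Jaccard index J = |X∩Y|/|X∪Y| and a scheme
(match a = 1, mismatch b = −1, gap gp = −1):

- pair similarity: `b + (a − b)·J` (defaults: 2J − 1),
- warp similarity: `b·(1 − J)` (defaults: J − 1),
- gap: gp.

The warp formula is the generalization chosen so its range is [b, 0] for
any scheme: a warp-inserted repeat is never rewarded (ceiling 0) and at
worst costs a full mismatch. Under the defaults the two similarities obey
`pair = 2·warp + 1`. Scheme parameters are configurable (CLI YAML keys
`match`, `mismatch`, `gap`); every number quoted in the documentation
assumes the defaults.

## The four aligners

All four fill an (n+1)×(m+1) accumulated score matrix and trace back;
moves are diagonal (consume one event from each sequence), vertical
(consume from the seed only) and horizontal (consume from the synthetic
side only).

**DTW (global, warping).** Borders other than A₀,₀ = 0 are −∞, forcing
first-index matching; traceback starts at A[n,m], forcing last-index
matching; there are no gaps — vertical/horizontal moves *repeat* the
stalled sequence's current event (a 1-to-n match). Diagonal moves score
the pair similarity; warp moves score the warp similarity. Scoring the
warp moves with the penalized repeat formula (rather than reusing the
pair formula on all three moves) is the design choice that makes the
matrix optimum equal the alignment score actually reported — it is the
only reading that reproduces the worked values (e.g. S_n = 0.75 for the
four-event deletion scenario) and keeps self-alignment at exactly S_n = 1.

**NWA (global, gaps).** Standard Needleman-Wunsch: borders i·gp / j·gp,
non-diagonal moves emit gap columns scored gp.

**SWA / DTWL (local).** Same move/score structure as NWA / DTW
respectively, but any cell whose best accumulated score would be negative
is floored to 0, and traceback starts at the matrix maximum and stops at
the first zero cell (the zero cell is not part of the alignment; an
all-zero matrix yields the empty alignment with raw score 0).

Reported quantities: raw score (sum of column scores = the DP optimum),
S_n = raw / N with N the *seed* length, and for local alignments the
coverage C = (max seed index − min seed index + 1)/N over the columns.
Coverage counts the *span*: a seed event bridged by an internal gap
column still lies inside the aligned region, so a gap-bridged end-to-end
alignment has C = 1.

### Determinism and ties

Co-optimal paths are common (scores are small rationals). Fill-time move
selection prefers diagonal, then vertical, then horizontal; the local
traceback start among tied maxima takes the largest (i, j) in row-major
order by default (`tiebreak="last"`; `"first"` exposed as an option).
Raw scores, S_n, and matrix values are tie-invariant; emitted paths —
and therefore local *coverage* — are not. A known consequence: in the
five-event deletion scenario SWA has two co-optimal paths (raw 3), one
gap-bridged with full coverage and one contiguous 3-match run; the
diagonal-preferring rule emits the latter (C = 0.6). S_n = 0.60 either
way. Scores are computed in float arithmetic without intermediate
rounding; display rounds to 3 decimals; tie/equality comparisons use a
1e−9 guard.

### Dominance properties — what is and is not guaranteed

Provable, and asserted as invariants: NWA ≥ REF-global (the reference
path is a feasible NWA path); SWA ≥ REF-local and DTWL ≥ REF-local (the
reference run is a feasible local path); DTWL ≥ SWA on raw scores (every
gap column, scored gp, trades for a warp column scored ≥ gp, and local
paths may start/end anywhere).

**DTW ≥ NWA is not a theorem.** The gap-to-warp trade works only for
*internal* gaps: a DTW path must begin and end with a diagonal pair
(first/last-index matching), so when the optimal NWA path uses a terminal
gap — typically because a mutation hit the first or last daily event —
DTW is forced to pay a mismatch pair where NWA paid a gap, and can score
strictly lower. Empirically this is rare (≈4% of records in the benchmark
suite, concentrated at short seeds), which is consistent with published
comparisons observing DTW ≥ NWA on every tested record without claiming
it in general. The conditional form is provable and is what the property
suite asserts: DTW ≥ NWA whenever NWA's optimal path starts and ends with
pair columns. Similarly, DTWL ≥ SWA holds on raw scores but not on the
lexicographic (C, S_n) ordering — SWA may bridge a wider seed span with
gaps than the warp path covers.

### Test oracle

`brute_force_best_alignment` exhaustively enumerates every legal path for
each mode (global paths corner-to-corner; local paths between arbitrary
cells, floored at the empty alignment) and returns the maximal raw score.
It shares no code with the DP fill or traceback and is capped at length 7
(exponential enumeration). The DP aligners are certified against it on
hundreds of random small instances, including multi-code events.

## Synthetic benchmark data

**Seed generation** emulates the encounter structure of real diagnosis
extracts. Defaults: a 582-code vocabulary (the size of a
period-truncated diagnosis grouping); 40% of days carry 2–3 base codes
(multi-diagnosis or multi-visit days), the rest one; one chronic-style
code recurs on max(2, 0.3·n) distinct days; one acute-style code occurs
exactly once. The fractions are a design choice made once for realism —
real records show a mix of sparse single-diagnosis days and code-dense
encounter days with recurring chronic conditions. Deterministic given an
integer seed.

What the generator does **not** emulate: real inter-visit time
statistics, code co-occurrence structure (comorbidity), coding-practice
drift, or the empirical record-length distribution (length is a
parameter, not sampled). Passing benchmarks therefore demonstrate
correctness of the aligners and the evaluation machinery under
controlled, provenance-known mutations — not clinical performance on
real EHR data.

**Mutation operations** at two levels — daily event and event block of
length max(2, ⌊n/10⌋) (floor chosen as the conservative integer reading;
for multi-operation rows the block length is recomputed from the current,
possibly already-shortened sequence, since the published rule is defined
only per seed):

- *delete*: remove the chosen event (or block);
- *update (daily)*: replace one code with a vocabulary code not already
  present, or — only when the event has > 1 codes — remove one code;
  replace/remove chosen with probability ½ when both are legal;
- *update (block)*: replace every event in the block with freshly drawn
  events of the same per-day code count;
- *switch*: swap the full code sets of two distinct positions (adjacent
  allowed), or two disjoint equal-length blocks.

Every random choice is recorded in an `Operation`; replaying the
provenance on the seed reproduces the synthetic sequence bit-for-bit
(property-tested). The default design applies 20 operation combinations
(`x`, `x x`, `u`, …, `X U S`), each row left-to-right on the already-
mutated sequence with positions re-drawn per operation.

## Reference alignments

The baseline the optimizing aligners are measured against is derived from
provenance, not from any search. Each synthetic position keeps an index
back to the seed position it descends from; only deletions remove
entries — updated and switched positions keep their positional identity
(their content changed or moved, but the slot still descends from the
same seed slot). The global reference pairs every mapped position
(scored by Jaccard, so updates and switches surface as partial or full
mismatches) and emits a gap for every deleted seed position. This
provenance-derived construction — not a naive positional overlay — is
what makes a single deletion score (N − 2)/N rather than collapsing all
downstream positions to mismatches.

The local reference is the longest contiguous run of *exact-match* pair
columns inside the global reference, earliest run on ties; its C and S_n
coincide by construction. A `min_pair_score` threshold can relax run
membership to admit partial-overlap pairs for multi-code events; the
default (exact matches only) is the definition under which the worked
values (e.g. C = S_n = 0.40 for a deletion among three repeats in a
five-event seed) hold.

## Evaluation harness

`run_benchmark` aligns each synthetic record with all four algorithms
plus both references; `summarize_comparison` counts better/equal/worse
per method pair (ties within 1e−9), ordering local results by coverage
first, then S_n, and separately counting the equal-coverage/better-score
case. Stored values are full precision; only display rounds (3 decimals).

## Limitations

- Diagnosis codes only; no medications, procedures, labs or notes.
- Order-based alignment: no banded/windowed DTW, affine gaps, or
  time-gap-aware costs.
- One optimal path is reported per alignment; co-optimal paths are
  acknowledged but not enumerated.
- The scoring system treats all codes alike; no acute/chronic or
  ontology-aware weighting.
- Published results computed on restricted real-patient records are not
  reproducible here; the benchmark runs entirely on synthetic records.
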