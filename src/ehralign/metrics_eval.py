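"""Benchmark evaluation: normalized scores, per-record result rows, and
pairwise method comparisons.

For every synthetic record derived from a seed, six results are
collected: the two global aligners (DTW, NWA) plus the global reference,
and the two local aligners (DTWL, SWA) plus the local reference.  All
scores are normalized by the seed length N so rows are comparable.
Comparison summaries count, for a method pair, how often the first
member scored better / equal / worse than the second — globally on S_n,
locally on (coverage, S_n) ordered lexicographically, with an extra count
for the "equal coverage but better similarity" case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align_global import dtw_align, nwa_align
from .align_local import dtwl_align, swa_align
from .records_io import EventSequence
from .reference import reference_global, reference_local
from .scoring import ScoringScheme
from .synthesis import SyntheticRecord

__all__ = [
    "BenchmarkRow",
    "ComparisonSummary",
    "normalized_score",
    "run_benchmark",
    "summarize_comparison",
    "rows_to_frame",
]

#: guard against float fuzz when counting ties between small rationals
DEFAULT_TOLERANCE = 1e-9


def normalized_score(raw: float, seed_length: int) -> float:
    """Normalize a raw alignment score by the seed-sequence length."""
    if seed_length < 1:
        raise ValueError("seed_length must be >= 1")
    return raw / seed_length


@dataclass(frozen=True)
class BenchmarkRow:
    """All six alignment results for one (seed, synthetic record) pair."""

    synthetic_id: int
    operation_label: str
    dtw_sn: float
    nwa_sn: float
    ref_sn: float
    dtwl_c: float
    dtwl_sn: float
    swa_c: float
    swa_sn: float
    ref_local_c: float
    ref_local_sn: float
    # raw scores kept for dominance checks (same denominator per row)
    dtw_raw: float = 0.0
    nwa_raw: float = 0.0
    ref_raw: float = 0.0
    dtwl_raw: float = 0.0
    swa_raw: float = 0.0
    ref_local_raw: float = 0.0


@dataclass
class ComparisonSummary:
    """better/equal/worse counts for one ordered method pair."""

    pair: str
    better: int = 0
    equal: int = 0
    worse: int = 0
    equal_coverage_better_score: int | None = None  # local pairs only

    @property
    def total(self) -> int:
        return self.better + self.equal + self.worse


def run_benchmark(
    seed: EventSequence,
    records: Sequence[SyntheticRecord],
    scheme: ScoringScheme = ScoringScheme(),
    labels: Sequence[str] | None = None,
) -> list[BenchmarkRow]:
    """Align every synthetic record to its seed with all four algorithms
    plus both references; one row per record."""
    rows = []
    for k, record in enumerate(records, start=1):
        label = labels[k - 1] if labels is not None else " ".join(
            "xus"[["delete", "update", "switch"].index(op.kind)].upper()
            if op.level == "block"
            else "xus"[["delete", "update", "switch"].index(op.kind)]
            for op in record.provenance
        )
        dtw = dtw_align(seed, record.sequence, scheme)
        nwa = nwa_align(seed, record.sequence, scheme)
        ref = reference_global(seed, record, scheme).alignment
        dtwl = dtwl_align(seed, record.sequence, scheme)
        swa = swa_align(seed, record.sequence, scheme)
        ref_l = reference_local(seed, record, scheme).alignment
        rows.append(
            BenchmarkRow(
                synthetic_id=k,
                operation_label=label,
                dtw_sn=dtw.normalized_score,
                nwa_sn=nwa.normalized_score,
                ref_sn=ref.normalized_score,
                dtwl_c=dtwl.coverage,
                dtwl_sn=dtwl.normalized_score,
                swa_c=swa.coverage,
                swa_sn=swa.normalized_score,
                ref_local_c=ref_l.coverage,
                ref_local_sn=ref_l.normalized_score,
                dtw_raw=dtw.raw_score,
                nwa_raw=nwa.raw_score,
                ref_raw=ref.raw_score,
                dtwl_raw=dtwl.raw_score,
                swa_raw=swa.raw_score,
                ref_local_raw=ref_l.raw_score,
            )
        )
    return rows


def _count(pairs, tol: float) -> tuple[int, int, int]:
    better = equal = worse = 0
    for a, b in pairs:
        if a > b + tol:
            better += 1
        elif a < b - tol:
            worse += 1
        else:
            equal += 1
    return better, equal, worse


def summarize_comparison(
    rows: Sequence[BenchmarkRow], tolerance: float = DEFAULT_TOLERANCE
) -> dict[str, ComparisonSummary]:
    """Pairwise method comparisons over a benchmark suite.

    Global pairs compare S_n; local pairs compare (coverage, S_n)
    lexicographically and additionally report the count of rows with
    equal coverage but a strictly better score.
    """
    if not rows:
        raise ValueError("cannot summarize an empty benchmark")
    out: dict[str, ComparisonSummary] = {}
    for pair, getter in (
        ("dtw_vs_ref", lambda r: (r.dtw_sn, r.ref_sn)),
        ("nwa_vs_ref", lambda r: (r.nwa_sn, r.ref_sn)),
        ("dtw_vs_nwa", lambda r: (r.dtw_sn, r.nwa_sn)),
    ):
        b, e, w = _count([getter(r) for r in rows], tolerance)
        out[pair] = ComparisonSummary(pair, b, e, w)

    for pair, getter in (
        ("dtwl_vs_ref", lambda r: ((r.dtwl_c, r.dtwl_sn), (r.ref_local_c, r.ref_local_sn))),
        ("swa_vs_ref", lambda r: ((r.swa_c, r.swa_sn), (r.ref_local_c, r.ref_local_sn))),
        ("dtwl_vs_swa", lambda r: ((r.dtwl_c, r.dtwl_sn), (r.swa_c, r.swa_sn))),
    ):
        better = equal = worse = eq_cov_better = 0
        for r in rows:
            (c1, s1), (c2, s2) = getter(r)
            if abs(c1 - c2) <= tolerance:
                if s1 > s2 + tolerance:
                    better += 1
                    eq_cov_better += 1
                elif s1 < s2 - tolerance:
                    worse += 1
                else:
                    equal += 1
            elif c1 > c2 + tolerance:
                better += 1
            else:
                worse += 1
        out[pair] = ComparisonSummary(pair, better, equal, worse, eq_cov_better)
    return out


def rows_to_frame(rows: Sequence[BenchmarkRow]) -> pd.DataFrame:
    """Benchmark rows as a DataFrame (scores rounded to 3 decimals for
    display; stored rows keep full precision)."""
    df = pd.DataFrame(
        {
            "id": [r.synthetic_id for r in rows],
            "operation": [r.operation_label for r in rows],
            "dtw_sn": [r.dtw_sn for r in rows],
            "nwa_sn": [r.nwa_sn for r in rows],
            "ref_sn": [r.ref_sn for r in rows],
            "dtwl_c": [r.dtwl_c for r in rows],
            "dtwl_sn": [r.dtwl_sn for r in rows],
            "swa_c": [r.swa_c for r in rows],
            "swa_sn": [r.swa_sn for r in rows],
            "ref_local_c": [r.ref_local_c for r in rows],
            "ref_local_sn": [r.ref_local_sn for r in rows],
        }
    )
    return df.round(3)
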