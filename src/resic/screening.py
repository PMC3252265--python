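"""Co-occurrence screening of alteration events before ordering analysis.

A temporal order between two events is only meaningful if the events
co-occur in the same tumors; mutually exclusive events likely belong to
separate disease routes.  Pairs are screened with a one-sided (enrichment)
Fisher's exact test at p <= 0.05, uncorrected by default, and both events
and their co-occurrence must each exceed 5% of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import EventMatrix

__all__ = [
    "ContingencyTable",
    "PairScreenResult",
    "EventTriple",
    "fisher_one_sided",
    "fisher_one_sided_many",
    "screen_pairs",
    "screen_triples",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 sample counts: both altered / only first / only second / neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class PairScreenResult:
    event_a: str
    event_b: str
    p_value: float
    freq_a: float
    freq_b: float
    joint_freq: float
    passes: bool


@dataclass(frozen=True)
class EventTriple:
    """A screened pair plus a third event correlated with >= 1 member."""

    pair: tuple[str, str]
    third: str

    @property
    def events(self) -> tuple[str, str, str]:
        return (*self.pair, self.third)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail Fisher exact p-value for co-occurrence enrichment.

    Exact hypergeometric probability of observing >= n11 doubly-altered
    samples given the table margins.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    return float(
        fisher_one_sided_many([table.n11], [table.n10], [table.n01], [table.n00])[0]
    )


def fisher_one_sided_many(n11, n10, n01, n00) -> "np.ndarray":
    """Vectorized one-sided Fisher p-values for parallel 2x2 tables.

    The one-sided (enrichment) Fisher exact test is the hypergeometric
    upper tail at n11 given the table margins.
    """
    n11 = np.asarray(n11, dtype=np.int64)
    n10 = np.asarray(n10, dtype=np.int64)
    n01 = np.asarray(n01, dtype=np.int64)
    n00 = np.asarray(n00, dtype=np.int64)
    total = n11 + n10 + n01 + n00
    return stats.hypergeom.sf(n11 - 1, total, n11 + n10, n11 + n01)


def _pair_table(matrix: EventMatrix, a: str, b: str) -> ContingencyTable:
    alt_a = matrix.altered(a).to_numpy()
    alt_b = matrix.altered(b).to_numpy()
    return ContingencyTable(
        n11=int((alt_a & alt_b).sum()),
        n10=int((alt_a & ~alt_b).sum()),
        n01=int((~alt_a & alt_b).sum()),
        n00=int((~alt_a & ~alt_b).sum()),
    )


def screen_pairs(
    matrix: EventMatrix,
    p_cut: float = 0.05,
    freq_cut: float = 0.05,
    bonferroni: bool = False,
) -> list[PairScreenResult]:
    """Screen all unordered event pairs for positive co-occurrence.

    An alteration means level >= 1.  A pair passes when p <= p_cut (with
    p_cut divided by the number of pairs if ``bonferroni``), and both
    marginal frequencies and the joint frequency are strictly > freq_cut.
    Results cover every pair and are sorted by p-value.
    """
    ids = matrix.event_ids
    if len(ids) < 2:
        raise ValueError("need at least two events to screen pairs")
    pairs = list(combinations(ids, 2))
    cut = p_cut / len(pairs) if bonferroni else p_cut
    results = []
    for a, b in pairs:
        t = _pair_table(matrix, a, b)
        p = fisher_one_sided(t)
        fa = matrix.marginal_frequency(a)
        fb = matrix.marginal_frequency(b)
        joint = t.n11 / t.total
        passes = (p <= cut) and (fa > freq_cut) and (fb > freq_cut) and (
            joint > freq_cut
        )
        results.append(PairScreenResult(a, b, p, fa, fb, joint, passes))
    return sorted(results, key=lambda r: (r.p_value, r.event_a, r.event_b))


def screen_triples(
    matrix: EventMatrix,
    passing_pairs: list[PairScreenResult],
    p_cut: float = 0.05,
    freq_cut: float = 0.05,
    require_both: bool = False,
) -> list[EventTriple]:
    """For each passing pair, find third events to test in three-way analyses.

    A third event qualifies when it passes the same pair screen against at
    least one pair member (or both, if ``require_both``).  Each
    (pair, third) combination is emitted once.
    """
    if not passing_pairs:
        return []
    all_results = {
        frozenset((r.event_a, r.event_b)): r
        for r in screen_pairs(matrix, p_cut=p_cut, freq_cut=freq_cut)
    }
    triples = []
    seen = set()
    for pr in passing_pairs:
        if not pr.passes:
            continue
        a, b = pr.event_a, pr.event_b
        for c in matrix.event_ids:
            if c in (a, b):
                continue
            with_a = all_results[frozenset((a, c))].passes
            with_b = all_results[frozenset((b, c))].passes
            ok = (with_a and with_b) if require_both else (with_a or with_b)
            key = (frozenset((a, b)), c)
            if ok and key not in seen:
                seen.add(key)
                triples.append(EventTriple(pair=(a, b), third=c))
    return triples


def screen_to_tsv(
    results: list[PairScreenResult], path: str | Path
) -> None:
    """Write pair-screen results as TSV."""
    pd.DataFrame(
        [
            {
                "event_a": r.event_a,
                "event_b": r.event_b,
                "p_value": r.p_value,
                "freq_a": r.freq_a,
                "freq_b": r.freq_b,
                "joint_freq": r.joint_freq,
                "passes": r.passes,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
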