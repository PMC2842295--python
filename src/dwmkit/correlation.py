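"""Gapped-dinucleotide deviation statistics over a site alignment.

For every pair of motif columns ``i < j`` and every dinucleotide ``(a, b)``
the observed number of sites carrying that dinucleotide is compared with the
column-independence expectation ``E = N * w_ai * w_bj``; the standard
deviation of the count under independence is ``sqrt(N p (1 - p))`` with
``p = w_ai * w_bj``.  A record is *significant* when the observed count
deviates from E by strictly more than two standard deviations, and
*abundant* when either the observed or the expected count reaches 30% of the
number of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix_model import (
    NUCLEOTIDES,
    Pwm,
    SiteAlignment,
    build_pwm,
    dinucleotide_counts,
)

SIGNIFICANCE_SIGMA = 2.0
ABUNDANCE_FRACTION = 0.3


@dataclass(frozen=True)
class PairDeviation:
    """Observed/expected statistics for one column pair and one dinucleotide."""

    i: int
    j: int  # i < j
    alpha: str
    beta: str
    expected: float
    sigma: float
    n_obs: int
    z: float
    significant: bool
    abundant: bool

    @property
    def gap(self) -> int:
        return self.j - self.i


@dataclass
class CorrelationSummary:
    """Counts of flagged deviation records for one factor."""

    n_records: int
    n_significant: int
    n_significant_abundant: int
    flagged_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_flagged_pairs(self) -> int:
        return len(self.flagged_pairs)


@dataclass
class GapHistogram:
    """Per-gap counts of flagged pairs with an availability correction.

    The availability of gap ``g`` for one motif of length ``L`` is
    ``max(L - g, 0)`` (the number of column pairs at that separation); the
    normalised rate divides the flag count by the summed availability.
    """

    counts: dict[int, int]
    availability: dict[int, int]
    rates: dict[int, float]


def pair_deviation_stats(
    alignment: SiteAlignment, pwm: Pwm | None = None, pseudocount: float = 1.0
) -> list[PairDeviation]:
    """Deviation records for all 16 * L(L-1)/2 (pair, dinucleotide) combinations.

    The Pwm supplying the independence expectation should be built from the
    same alignment; when omitted it is built here with ``pseudocount``.
    """
    if alignment.count < 1:
        raise ValueError("deviation statistics require at least one sequence")
    if pwm is None:
        pwm = build_pwm(alignment, pseudocount)
    if pwm.length != alignment.length:
        raise ValueError("Pwm length does not match the alignment")
    n = alignment.count
    L = alignment.length
    codes = alignment.codes()
    m = dinucleotide_counts(codes, L)
    w = pwm.probs
    records: list[PairDeviation] = []
    for i in range(L):
        for j in range(i + 1, L):
            p = np.outer(w[i], w[j])
            expected = n * p
            sigma = np.sqrt(n * p * (1.0 - p))
            for a in range(4):
                for b in range(4):
                    obs = int(m[i, j, a, b])
                    e = float(expected[a, b])
                    s = float(sigma[a, b])
                    z = (obs - e) / s if s > 0 else 0.0
                    records.append(
                        PairDeviation(
                            i=i,
                            j=j,
                            alpha=NUCLEOTIDES[a],
                            beta=NUCLEOTIDES[b],
                            expected=e,
                            sigma=s,
                            n_obs=obs,
                            z=float(z),
                            significant=abs(obs - e) > SIGNIFICANCE_SIGMA * s,
                            abundant=max(obs, e) >= ABUNDANCE_FRACTION * n,
                        )
                    )
    return records


def flag_correlated_pairs(devs: Sequence[PairDeviation]) -> CorrelationSummary:
    """Summarise significant and significant-and-abundant records.

    The abundance filter is applied on top of significance: a column pair is
    flagged only when at least one of its dinucleotide records passes both.
    """
    flagged = sorted({(d.i, d.j) for d in devs if d.significant and d.abundant})
    return CorrelationSummary(
        n_records=len(devs),
        n_significant=sum(d.significant for d in devs),
        n_significant_abundant=sum(d.significant and d.abundant for d in devs),
        flagged_pairs=flagged,
    )


def gap_distribution(
    flagged: Sequence[PairDeviation], motif_lengths: Sequence[int]
) -> GapHistogram:
    """Distribution of gaps among flagged records, corrected for availability."""
    counts: dict[int, int] = {}
    for d in flagged:
        if d.gap < 1:
            raise ValueError("gaps must be >= 1")
        counts[d.gap] = counts.get(d.gap, 0) + 1
    max_gap = max((L - 1 for L in motif_lengths), default=0)
    availability = {
        g: sum(max(L - g, 0) for L in motif_lengths) for g in range(1, max_gap + 1)
    }
    rates = {
        g: counts.get(g, 0) / avail for g, avail in availability.items() if avail > 0
    }
    return GapHistogram(counts=counts, availability=availability, rates=rates)


@dataclass
class CorrelationCensus:
    """Aggregate deviation counts across a collection of factors.

    Column pairs and dinucleotide records are counted separately because the
    two units differ (16 records per column pair).
    """

    column_pairs_examined: int
    records_examined: int
    significant_records: int
    significant_abundant_records: int
    per_factor_flagged_pairs: dict[str, int]
    factors_with_3plus_pairs: list[str]


def correlation_census(
    alignments: Mapping[str, SiteAlignment], pseudocount: float = 1.0
) -> CorrelationCensus:
    """Run the deviation analysis for every factor and aggregate the counts."""
    pairs_examined = 0
    records_examined = 0
    significant = 0
    significant_abundant = 0
    per_factor: dict[str, int] = {}
    for factor, alignment in alignments.items():
        devs = pair_deviation_stats(alignment, pseudocount=pseudocount)
        summary = flag_correlated_pairs(devs)
        L = alignment.length
        pairs_examined += L * (L - 1) // 2
        records_examined += summary.n_records
        significant += summary.n_significant
        significant_abundant += summary.n_significant_abundant
        per_factor[factor] = summary.n_flagged_pairs
    factors = sorted(
        (f for f, k in per_factor.items() if k >= 3),
        key=lambda f: -per_factor[f],
    )
    return CorrelationCensus(
        column_pairs_examined=pairs_examined,
        records_examined=records_examined,
        significant_records=significant,
        significant_abundant_records=significant_abundant,
        per_factor_flagged_pairs=per_factor,
        factors_with_3plus_pairs=factors,
    )
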