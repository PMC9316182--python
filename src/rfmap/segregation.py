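"""Chi-square goodness-of-fit tests for fertile:sterile segregation ratios.

A single dominant restorer allele predicts a 3:1 fertile:sterile ratio in
the F2.  Counts are tested per family and pooled over families with a
1-df chi-square goodness-of-fit test.  The Yates continuity correction,
(|O - E| - 0.5)^2 / E without clamping at zero, is applied by default;
the plain (O - E)^2 / E statistic is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats


@dataclass
class SegregationRecord:
    """Observed fertile/sterile counts for one F2 family."""

    family: str
    n_fertile: int
    n_sterile: int
    expected_ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_fertile < 0 or self.n_sterile < 0:
            raise ValueError(f"{self.family}: counts must be non-negative")
        if self.n_fertile + self.n_sterile < 1:
            raise ValueError(f"{self.family}: at least one plant required")
        if min(self.expected_ratio) <= 0:
            raise ValueError(f"{self.family}: ratio terms must be positive")

    @property
    def n_total(self) -> int:
        return self.n_fertile + self.n_sterile


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: tuple[float, float]


def chi_square_p(statistic: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def chi_square_gof(
    record: SegregationRecord, continuity_correction: bool = True
) -> ChiSquareResult:
    """Goodness-of-fit test of observed counts against the expected ratio.

    Expected counts are derived from the component sum
    ``n_fertile + n_sterile``, never from a separately supplied total.
    With the continuity correction each term is (|O - E| - 0.5)^2 / E;
    the (|O - E| - 0.5) difference is deliberately not clamped at zero,
    so near-perfect fits yield a small positive statistic.
    """
    n = record.n_total
    ratio_sum = record.expected_ratio[0] + record.expected_ratio[1]
    expected = (
        n * record.expected_ratio[0] / ratio_sum,
        n * record.expected_ratio[1] / ratio_sum,
    )
    statistic = 0.0
    for obs, exp in zip((record.n_fertile, record.n_sterile), expected):
        diff = abs(obs - exp)
        if continuity_correction:
            diff -= 0.5
        statistic += diff * diff / exp
    return ChiSquareResult(statistic, 1, chi_square_p(statistic, 1), expected)


def segregation_report(
    records: list[SegregationRecord],
    continuity_correction: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family chi-square tests plus a pooled row summing all counts.

    The ``fits_ratio`` column flags families whose p-value exceeds
    ``alpha`` (i.e. the stated ratio is not rejected).
    """
    if not records:
        raise ValueError("at least one family record required")
    ratio = records[0].expected_ratio
    pooled = SegregationRecord(
        "Total",
        sum(r.n_fertile for r in records),
        sum(r.n_sterile for r in records),
        expected_ratio=ratio,
    )
    rows = []
    for rec in [*records, pooled]:
        res = chi_square_gof(rec, continuity_correction=continuity_correction)
        rows.append(
            {
                "family": rec.family,
                "n_total": rec.n_total,
                "n_fertile": rec.n_fertile,
                "n_sterile": rec.n_sterile,
                "ratio": f"{rec.expected_ratio[0]:g}:{rec.expected_ratio[1]:g}",
                "chi2": res.statistic,
                "p_value": res.p_value,
                "fits_ratio": res.p_value > alpha,
            }
        )
    return pd.DataFrame(rows)
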