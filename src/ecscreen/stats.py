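"""Contingency-table and mean-comparison statistics for subgroup analysis.

The Pearson χ² statistic is computed directly from observed/expected counts
(with optional Yates continuity correction on 2×2 tables); the p-value
kernel is the regularized upper incomplete gamma function Q(df/2, x/2).
Group means are compared with Welch's unequal-variance two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

from .model import DegenerateTableError, EcsError


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, ...], ...]
    chi2: float
    df: int
    p_value: float
    yates: bool


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p_value: float


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution, Q(df/2, x/2)."""
    if x < 0:
        raise EcsError("chi-squared statistic must be non-negative")
    if df < 1:
        raise EcsError("degrees of freedom must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def pearson_chi2(table: Sequence[Sequence[int]], yates: bool = False) -> ContingencyResult:
    """Pearson chi-squared test of homogeneity on an r×k count table.

    ``yates`` applies the continuity correction |O−E| → max(|O−E|−0.5, 0),
    valid only on 2×2 tables.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise EcsError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise EcsError("contingency table counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("contingency table has a zero row or column marginal")
    if yates and obs.shape != (2, 2):
        raise EcsError("Yates correction applies to 2x2 tables only")

    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(
        table=tuple(tuple(int(v) for v in row) for row in np.asarray(table)),
        chi2=chi2,
        df=df,
        p_value=chi2_upper_tail(chi2, df),
        yates=yates,
    )


def carrier_table(carriers_a: int, n_a: int, carriers_b: int, n_b: int) -> list[list[int]]:
    """Build the 2×2 carriers/non-carriers table for two groups."""
    if carriers_a > n_a or carriers_b > n_b:
        raise EcsError("carrier count exceeds group size")
    return [[carriers_a, n_a - carriers_a], [carriers_b, n_b - carriers_b]]


def two_sided_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch's two-sided t-test comparing two groups of continuous values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EcsError("each group needs at least 2 observations for a t-test")
    res = sps.ttest_ind(a, b, equal_var=False)
    # identical constant groups: scipy returns nan; define t=0, p=1
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(getattr(res, "df", np.nan))
    if np.isnan(t):
        t, p = 0.0, 1.0
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
        t=t,
        df=df,
        p_value=p,
    )
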