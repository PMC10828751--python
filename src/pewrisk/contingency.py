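"""Contingency-table statistics for risk-score validation.

2x2 odds ratios with Woolf (log-normal) confidence intervals, Pearson
chi-square tests on r x k tables, and row percentages — the estimator layer
behind every factor-vs-risk-group and risk-group-vs-outcome comparison.

Zero cells are a hard error by default; the Haldane–Anscombe +0.5
correction is opt-in because silent corrections change published-style
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ZeroCellError(ValueError):
    """A cell required to be positive is zero; names the cell."""


class DegenerateTableError(ValueError):
    """A row or column (or the whole table) is empty."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts laid out rows = exposure levels (reference first),
    columns = (low risk, high risk) or (no event, event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or any(x != int(x) for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise DegenerateTableError("grand total is zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ContingencyTable:
    """r x k count matrix with labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need an r x k matrix with r, k >= 2")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise DegenerateTableError("grand total is zero")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    """One report row: OR with Woolf CI plus the Pearson chi-square test."""

    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    chi2_stat: float
    df: int
    p_value: float
    confidence_level: float = 0.95

    def __post_init__(self):
        if self.odds_ratio is not None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ValueError("CI must contain the point estimate")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _cells(t: TwoByTwoTable, haldane_anscombe: bool) -> tuple[float, float, float, float]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if haldane_anscombe:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    for name, x in zip("abcd", (a, b, c, d)):
        if x == 0:
            raise ZeroCellError(
                f"cell {name} is zero; set haldane_anscombe=True to add 0.5 to every cell"
            )
    return a, b, c, d


def odds_ratio(t: TwoByTwoTable, haldane_anscombe: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c)."""
    a, b, c, d = _cells(t, haldane_anscombe)
    return (a * d) / (b * c)


def woolf_ci(
    t: TwoByTwoTable, level: float = 0.95, haldane_anscombe: bool = False
) -> tuple[float, float]:
    """Woolf confidence interval: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a, b, c, d = _cells(t, haldane_anscombe)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def pearson_chi2(
    t: ContingencyTable | TwoByTwoTable, yates: bool = False
) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom.

    Yates continuity correction (2x2 only) is off by default.
    """
    arr = t.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("a row or column total is zero")
    stat, _, df, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), int(df)


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if stat < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(stat, df))


def row_percentages(t: ContingencyTable | TwoByTwoTable) -> np.ndarray:
    """Each cell as a fraction of its row total; rows sum to 1."""
    arr = t.as_array()
    totals = arr.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise DegenerateTableError("a row total is zero")
    return arr / totals


def effect_estimate(
    t: TwoByTwoTable,
    level: float = 0.95,
    haldane_anscombe: bool = False,
    yates: bool = False,
) -> EffectEstimate:
    """OR + Woolf CI + Pearson chi-square in one report row."""
    stat, df = pearson_chi2(t, yates=yates)
    lo, hi = woolf_ci(t, level=level, haldane_anscombe=haldane_anscombe)
    return EffectEstimate(
        odds_ratio=odds_ratio(t, haldane_anscombe=haldane_anscombe),
        ci_low=lo,
        ci_high=hi,
        chi2_stat=stat,
        df=df,
        p_value=chi2_pvalue(stat, df),
        confidence_level=level,
    )


def chi2_only(t: ContingencyTable, yates: bool = False) -> EffectEstimate:
    """Chi-square test for an r x k table where an OR is not applicable."""
    stat, df = pearson_chi2(t, yates=yates)
    return EffectEstimate(
        odds_ratio=None,
        ci_low=None,
        ci_high=None,
        chi2_stat=stat,
        df=df,
        p_value=chi2_pvalue(stat, df),
    )
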