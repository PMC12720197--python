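"""Small-sample exact statistics.

Everything downstream (performance tables, utility rates, cohort
descriptives) funnels its uncertainty through this module: Clopper-Pearson
exact binomial intervals, Fisher's exact test and Pearson's chi-square for
contingency tables.  The Clopper-Pearson interval is the only interval
offered on purpose: it guarantees at least nominal coverage at the small
verified-sample sizes typical of partially verified diagnostic cohorts,
where Wald or Wilson intervals can undercover badly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Interval",
    "Proportion",
    "ContingencyTable",
    "clopper_pearson",
    "proportion_with_ci",
    "fisher_exact_2x2",
    "pearson_chi2",
    "association_pvalue",
    "format_p",
]


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval on a proportion, as fractions in [0, 1]."""

    low: float
    high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError(f"interval bounds out of order: ({self.low}, {self.high})")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")

    def as_percent(self) -> tuple[float, float]:
        return 100.0 * self.low, 100.0 * self.high


@dataclass(frozen=True)
class Proportion:
    """x/n with its exact interval; the universal result carrier.

    ``estimate`` is always the plain ratio ``numerator / denominator``; the
    interval is Clopper-Pearson at ``ci.confidence``.
    """

    numerator: int
    denominator: int
    estimate: float
    ci: Interval

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be a positive integer")
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("numerator must satisfy 0 <= x <= n")
        if not np.isclose(self.estimate, self.numerator / self.denominator):
            raise ValueError("estimate must equal numerator / denominator")
        if not (self.ci.low <= self.estimate + 1e-12 and self.estimate - 1e-12 <= self.ci.high):
            raise ValueError("interval must bracket the point estimate")

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "estimate": self.estimate,
            "ci_low": self.ci.low,
            "ci_high": self.ci.high,
            "confidence": self.ci.confidence,
        }


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with optional labels."""

    cells: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = field(default=())
    col_labels: tuple[str, ...] = field(default=())

    @classmethod
    def from_array(cls, a: Sequence[Sequence[int]], row_labels=(), col_labels=()) -> "ContingencyTable":
        cells = tuple(tuple(int(x) for x in row) for row in a)
        return cls(cells, tuple(row_labels), tuple(col_labels))

    def __post_init__(self) -> None:
        nrow = len(self.cells)
        if nrow < 2 or any(len(r) != len(self.cells[0]) for r in self.cells):
            raise ValueError("table must be rectangular with at least 2 rows")
        if len(self.cells[0]) < 2:
            raise ValueError("table must have at least 2 columns")
        if any(x < 0 for row in self.cells for x in row):
            raise ValueError("cell counts must be non-negative")
        if sum(x for row in self.cells for x in row) == 0:
            raise ValueError("table must have a positive grand total")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.cells), len(self.cells[0])


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> Interval:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion.

    The bounds are Beta-distribution quantiles: the lower bound is the
    alpha/2 quantile of Beta(x, n - x + 1) (0 when x = 0) and the upper
    bound the 1 - alpha/2 quantile of Beta(x + 1, n - x) (1 when x = n).
    Equivalently, each bound is the success probability at which the
    observed count becomes just tail-improbable at level alpha/2.

    Parameters
    ----------
    x : int
        Number of successes, 0 <= x <= n.
    n : int
        Number of trials, n >= 1.
    confidence : float
        Two-sided confidence level in (0, 1); default 0.95.
    """
    x, n = int(x), int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return Interval(low=low, high=high, confidence=confidence)


def proportion_with_ci(x: int, n: int, confidence: float = 0.95) -> Proportion:
    """Bundle x/n with its Clopper-Pearson interval."""
    ci = clopper_pearson(x, n, confidence)
    return Proportion(numerator=int(x), denominator=int(n), estimate=x / n, ci=ci)


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass criterion: the p-value sums the hypergeometric
    probabilities of every table with the observed margins whose probability
    does not exceed that of the observed table (ties within a small relative
    tolerance counted in).  Other two-sided conventions exist (e.g. doubling
    the one-sided tail); this is the one used by R's ``fisher.test``.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    _, p = stats.fisher_exact(t.to_array(), alternative="two-sided")
    return float(min(p, 1.0))


def pearson_chi2(
    table: ContingencyTable | Sequence[Sequence[int]],
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square test of independence for an r x c table.

    Returns ``(statistic, p_value)`` with (r-1)(c-1) degrees of freedom.
    With ``continuity_correction`` (Yates), applicable to 2x2 tables only,
    the statistic is sum((|O - E| - 0.5)^2 / E).

    Raises
    ------
    ValueError
        If any margin is zero (an expected count of zero makes the
        statistic undefined).
    """
    t = _as_table(table)
    a = t.to_array()
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin: expected counts undefined")
    if continuity_correction and t.shape != (2, 2):
        raise ValueError("continuity correction applies to 2x2 tables only")
    chi2, p, _, _ = stats.chi2_contingency(a, correction=continuity_correction)
    return float(chi2), float(p)


def association_pvalue(table: ContingencyTable | Sequence[Sequence[int]]) -> tuple[float, str]:
    """Default association test for a cohort stratifier table.

    For 2x2 tables: continuity-corrected chi-square, falling back to
    Fisher's exact test when any expected cell count is below 5.  For wider
    tables: plain Pearson chi-square.  Returns ``(p_value, test_name)``.
    """
    t = _as_table(table)
    a = t.to_array()
    if t.shape == (2, 2):
        expected = np.outer(a.sum(axis=1), a.sum(axis=0)) / a.sum()
        if (expected < 5).any():
            return fisher_exact_2x2(t), "fisher_exact"
        _, p = pearson_chi2(t, continuity_correction=True)
        return p, "chi2_continuity_corrected"
    _, p = pearson_chi2(t, continuity_correction=False)
    return p, "chi2"


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print them.

    Two significant figures, with a "<0.001" floor and a ">0.9" ceiling;
    full precision is always retained in the JSON side of a report.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p < 0.001:
        return "<0.001"
    if p > 0.9:
        return ">0.9"
    return f"{p:.2g}"


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable.from_array(table)
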