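"""Group-comparison statistics for the two Ch4 groups.

Continuous variables are summarized as median (IQR) and compared with the
Kruskal-Wallis rank test; categorical variables (symptom present/absent,
subtype membership) with the uncorrected Pearson chi-square.  A two-sample
t-test power calculation (noncentral-t) covers the study-size arithmetic.

The chi-square deliberately applies NO Yates continuity correction and never
falls back to Fisher's exact test at small counts — that is the convention the
rest of the package's tables are built on; Fisher's exact is available as an
explicit alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "binarize_symptom",
    "pearson_chi2",
    "fisher_exact",
    "kruskal_wallis",
    "median_iqr",
    "two_sample_power",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Group x symptom 2x2 counts: a/b = group 1 present/absent, c/d = group 2."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("present", "absent")

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def binarize_symptom(item_score: float) -> bool:
    """True iff a 0-4 ordinal item is scored 1 or more (symptom present)."""
    if not 0 <= item_score <= 4:
        raise ValueError(f"item score {item_score} outside the 0-4 range")
    return item_score >= 1


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, df = 1."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError(
            "a zero row or column margin makes the chi-square statistic undefined"
        )
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(res.statistic), df=1, p_value=float(res.pvalue),
        method="pearson-chi2 (no continuity correction)",
    )


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test — the explicit small-count alternative."""
    stat, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(statistic=float(stat), df=1, p_value=float(p),
                      method="fisher-exact")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square p, df = k-1).

    Used even for two groups, in place of a rank-sum test, so that every
    continuous comparison in the package goes through one method.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = [np.asarray(g, dtype=float) for g in groups]
    for g in clean:
        if g.size < 1:
            raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(clean)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: rank statistic is degenerate")
    h, p = sps.kruskal(*clean)
    return TestResult(statistic=float(h), df=len(groups) - 1, p_value=float(p),
                      method="kruskal-wallis")


def median_iqr(values) -> tuple[float, float, float]:
    """(median, 25th, 75th) percentiles with linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def two_sample_power(n1: int, n2: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at standardized difference d.

    Noncentrality d / sqrt(1/n1 + 1/n2), df = n1 + n2 - 2, exact noncentral-t
    tail probabilities.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    df = n1 + n2 - 2
    ncp = d / np.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)
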