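"""Statistical comparisons over the subjects x conditions grid.

One-way repeated-measures ANOVA (sphericity assumed; Greenhouse-Geisser off
by default since no correction is applied in the study design this mirrors),
Bonferroni-adjusted paired t-tests for post hoc pairwise comparisons, and
Cochran's Q for dichotomous outcomes (short tunnel, wall breakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepeatedMeasures",
    "BinaryRepeated",
    "TestResult",
    "rm_anova",
    "bonferroni_pairs",
    "cochran_q",
]


@dataclass
class RepeatedMeasures:
    """Complete within-subject data: rows = subjects, columns = levels."""

    values: np.ndarray
    level_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x levels matrix")
        n, k = self.values.shape
        if k < 2 or n < 3:
            raise ValueError(f"need >=3 subjects and >=2 levels, got {n} x {k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite cells are not allowed")
        if self.level_names is None:
            self.level_names = [f"L{j}" for j in range(k)]

    @classmethod
    def from_long(cls, df, subject: str, level: str, value: str) -> "RepeatedMeasures":
        wide = df.pivot(index=subject, columns=level, values=value)
        if wide.isna().any().any():
            raise ValueError("incomplete subjects x levels grid")
        return cls(wide.to_numpy(), [str(c) for c in wide.columns])


@dataclass
class BinaryRepeated:
    """0/1 within-subject indicators: rows = subjects, columns = levels."""

    indicators: np.ndarray
    level_names: list[str] | None = None

    def __post_init__(self):
        arr = np.asarray(self.indicators)
        if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
            raise ValueError("indicators must be a 2D 0/1 matrix")
        self.indicators = arr.astype(int)
        if self.level_names is None:
            self.level_names = [f"L{j}" for j in range(arr.shape[1])]


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_p: float | None = None
    label: str = ""
    flags: list[str] = field(default_factory=list)


def rm_anova(data: RepeatedMeasures) -> TestResult:
    """One-way within-subjects F test.

    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1)),
    with the subject main effect removed. Sphericity is assumed.
    """
    x = data.values
    n, k = x.shape
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    flags: list[str] = []
    if ms_err <= 0.0:
        if ms_cond <= 0.0:
            return TestResult(0.0, (df1, df2), 1.0, flags=["degenerate: zero variance"])
        flags.append("degenerate: zero error variance")
        return TestResult(float("inf"), (df1, df2), 0.0, flags=flags)
    f = ms_cond / ms_err
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, df2), p, flags=flags)


def bonferroni_pairs(data: RepeatedMeasures) -> list[TestResult]:
    """All k(k-1)/2 two-sided paired t-tests with Bonferroni-adjusted p
    (adjusted_p = min(1, p * m), m = number of pairs in the family)."""
    x = data.values
    n, k = x.shape
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = x[:, i] - x[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                stat, p, flags = 0.0, 1.0, ["degenerate: identical columns"]
            else:
                stat, p, flags = float("inf"), 0.0, ["degenerate: zero-variance difference"]
        else:
            t = sps.ttest_rel(x[:, i], x[:, j])
            stat, p, flags = float(t.statistic), float(t.pvalue), []
        out.append(TestResult(
            stat, (n - 1,), p, adjusted_p=min(1.0, p * m),
            label=f"{data.level_names[i]} vs {data.level_names[j]}", flags=flags,
        ))
    return out


def cochran_q(data: BinaryRepeated) -> TestResult:
    """Cochran's Q for k related proportions.

    Q = k(k-1) * sum_j (C_j - T/k)^2 / (k*T - sum_i R_i^2), chi-square with
    k-1 df under the null of equal proportions across levels.
    """
    x = data.indicators
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    total = x.sum()
    denom = k * total - np.sum(row**2)
    if denom == 0:
        return TestResult(0.0, (k - 1,), 1.0,
                          flags=["degenerate: all rows constant"])
    q = k * (k - 1) * np.sum((col - total / k) ** 2) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult(float(q), (k - 1,), p)
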