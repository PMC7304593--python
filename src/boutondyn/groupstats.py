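"""Group comparisons: pooled two-sample t-test, two-sample KS, Pearson r.

The t-test is Student's pooled-variance form with df = n1 + n2 - 2 (for
two groups of 8 animals, df = 14), the Kolmogorov-Smirnov test uses the
asymptotic two-sided p-value, and Pearson's correlation reports the
two-sided p from the t transform. All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str             # t_unpaired | ks_two_sample | pearson
    df: float | None = None
    degenerate: bool = False   # e.g. zero pooled variance

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def t_unpaired(x, y) -> TestResult:
    """Student's (pooled-variance) unpaired two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled <= 0:
        # identical constant groups: no evidence of a difference
        return TestResult(statistic=0.0, p_value=1.0, test_name="t_unpaired",
                          df=float(df), degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      test_name="t_unpaired", df=float(df))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    D is the supremum of the absolute difference between the two
    empirical CDFs; used for comparing bouton size distributions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      test_name="ks_two_sample")


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      test_name="pearson", df=float(x.size - 2))


def results_table(results: dict[str, TestResult]) -> pd.DataFrame:
    """Comparison results as a table (statistic, df, p per comparison)."""
    rows = [
        {"comparison": name, "test": r.test_name, "statistic": r.statistic,
         "df": r.df, "p_value": r.p_value}
        for name, r in results.items()
    ]
    return pd.DataFrame(rows, columns=["comparison", "test", "statistic",
                                       "df", "p_value"])
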