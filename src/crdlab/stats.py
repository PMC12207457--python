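"""Hypothesis tests used by the study's analysis layer.

Three tests cover all reported comparisons: the one-sided Welch unequal-
variance t test (group-level quantities are strongly heteroskedastic
across treatments), Fisher's exact test on 2x2 success/behavior
contingency tables, and the two-way factorial ANOVA with interaction for
the 2x2 (delegation x number of choices) design.  The ANOVA uses Type II
sums of squares by default — cells are unbalanced — with Type III behind
a flag.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestResult",
    "welch_t",
    "fisher_exact",
    "anova_two_way",
    "results_frame",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alternative: str
    degrees_of_freedom: Optional[float] = None
    contrast: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float],
            alternative: str = "two-sided", contrast: str = "") -> TestResult:
    """Welch's unequal-variance t test with Satterthwaite df.

    ``alternative='greater'`` tests mean(a) > mean(b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both samples are constant; the t statistic is undefined")
    res = st.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(
        test_name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        degrees_of_freedom=float(res.df),
        contrast=contrast,
    )


def fisher_exact(contingency, alternative: str = "two-sided",
                 contrast: str = "") -> TestResult:
    """Fisher's exact test on a 2x2 table; the statistic is the odds ratio."""
    table = np.asarray(contingency, dtype=int)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("contingency cells must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    odds, p = st.fisher_exact(table, alternative=alternative)
    return TestResult(
        test_name="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        alternative=alternative,
        contrast=contrast,
    )


def anova_two_way(values: Sequence[float], factor_delegation: Sequence,
                  factor_choices: Sequence, ss_type: int = 2) -> pd.DataFrame:
    """Two-way factorial ANOVA with interaction on the 2x2 design.

    Returns a tidy frame with one row per effect (delegation, choices,
    interaction): sum of squares, df, F, and p.  ``ss_type`` selects Type
    II (default, appropriate for the unbalanced cells) or Type III sums of
    squares.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "delegation": [str(v) for v in factor_delegation],
        "choices": [str(v) for v in factor_choices],
    })
    counts = df.groupby(["delegation", "choices"]).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("all four design cells must be nonempty")
    model = smf.ols("value ~ C(delegation) * C(choices)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.rename(index={
        "C(delegation)": "delegation",
        "C(choices)": "choices",
        "C(delegation):C(choices)": "delegation:choices",
        "Residual": "residual",
    })
    out = table.reset_index().rename(columns={
        "index": "effect", "sum_sq": "sum_sq", "df": "df", "F": "F",
        "PR(>F)": "p_value",
    })
    if "Intercept" in set(out["effect"]):
        out = out[out["effect"] != "Intercept"].reset_index(drop=True)
    return out


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Uniform results table: one row per test."""
    return pd.DataFrame(
        {
            "test_name": [r.test_name for r in results],
            "contrast": [r.contrast for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.degrees_of_freedom for r in results],
            "p_value": [r.p_value for r in results],
            "alternative": [r.alternative for r in results],
        }
    )
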