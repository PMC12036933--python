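"""The study's statistical battery.

The unit of analysis is the bird: cell-level measurements are averaged
per bird before any test.  Group comparisons (statin vs control) use
pooled-variance Student t-tests (df = n1 + n2 − 2, matching the
reported df of 11 for 6 vs 7 birds); the two neuron populations within
the same birds are compared with a 2 (group) × 2 (population)
mixed-design ANOVA with post-hoc paired t-tests; families of descriptor
comparisons are corrected with the Benjamini–Hochberg step-up FDR; and
experimental covariates (ages, treatment duration) are screened against
outcomes with ordinary least-squares regressions.

The pooled (Student) rather than Welch t-test is a deliberate fidelity
choice — group variances are not assumed checked — and is documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "RegressionResult",
    "DegenerateDataError",
    "t_independent",
    "t_paired",
    "mixed_anova_2x2",
    "bh_fdr",
    "ols_regress",
]


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested test (zero variance,
    constant predictor, too few observations)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-tailed t-test.

    ``direction`` is the sign of (first group − second group); for group
    comparisons callers pass the statin group first.
    """

    statistic: float
    df: float
    p_value: float
    direction: int
    tails: int = 2


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise DegenerateDataError("non-finite values in test input")
    return a


def t_independent(x, y) -> TestResult:
    """Two-tailed pooled-variance (Student) t-test, df = n1 + n2 − 2."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    diff = float(np.mean(x) - np.mean(y))
    pooled = (np.var(x, ddof=1) * (len(x) - 1) + np.var(y, ddof=1) * (len(y) - 1))
    if pooled == 0.0:
        if diff == 0.0:
            return TestResult(0.0, len(x) + len(y) - 2, 1.0, 0)
        raise DegenerateDataError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), len(x) + len(y) - 2, float(p), int(np.sign(diff)))


def t_paired(x, y) -> TestResult:
    """Two-tailed paired t-test on the differences, df = n − 1."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise DegenerateDataError("paired samples must have equal length")
    if len(x) < 2:
        raise DegenerateDataError("need at least 2 pairs")
    d = x - y
    if np.var(d, ddof=1) == 0.0:
        if np.mean(d) == 0.0:
            return TestResult(0.0, len(d) - 1, 1.0, 0)
        raise DegenerateDataError("zero-variance differences with nonzero mean")
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), len(d) - 1, float(p), int(np.sign(np.mean(d))))


def mixed_anova_2x2(values, groups) -> pd.DataFrame:
    """2 (between: group) × 2 (within: neuron population) mixed ANOVA.

    Parameters
    ----------
    values : array-like, shape (n_subjects, 2)
        One row per bird, one column per within-subject level (both
        populations measured in the same tissue).
    groups : sequence of length n_subjects
        Between-subject labels with exactly two levels.

    Returns
    -------
    DataFrame indexed by effect (``group``, ``population``,
    ``interaction``) with columns ss, df1, df2, F, p.

    The group effect is tested against the between-subjects
    (subject-within-group) error stratum; the population effect and the
    interaction against the subject × population error stratum.  With
    unbalanced groups the marginal condition means are group-size
    weighted.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise DegenerateDataError("values must be (n_subjects, 2)")
    if not np.all(np.isfinite(y)):
        raise DegenerateDataError("missing within-level value for at least one subject")
    groups = np.asarray(groups)
    if len(groups) != len(y):
        raise DegenerateDataError("groups and values length mismatch")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise DegenerateDataError(f"need exactly 2 groups, got {len(levels)}")
    n_g = np.array([(groups == g).sum() for g in levels])
    if np.any(n_g < 2):
        raise DegenerateDataError("each group needs at least 2 subjects")
    n = len(y)

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = np.array([y[groups == g].mean() for g in levels])
    cond_mean = y.mean(axis=0)
    cell_mean = np.array([[y[groups == g, c].mean() for c in (0, 1)] for g in levels])

    ss_group = 2.0 * float(np.sum(n_g * (group_mean - grand) ** 2))
    ss_subj = 2.0 * float(
        sum(
            np.sum((subj_mean[groups == g] - group_mean[i]) ** 2)
            for i, g in enumerate(levels)
        )
    )
    ss_cond = float(n * np.sum((cond_mean - grand) ** 2))
    ss_inter = float(
        np.sum(
            n_g[:, None]
            * (cell_mean - group_mean[:, None] - cond_mean[None, :] + grand) ** 2
        )
    )
    gi = np.array([np.where(levels == g)[0][0] for g in groups])
    resid = y - cell_mean[gi] - subj_mean[:, None] + group_mean[gi][:, None]
    ss_err = float(np.sum(resid**2))

    df_subj = n - 2
    df_err = n - 2

    def _row(ss, df1, df2, ms_err):
        if ms_err == 0.0:
            f = 0.0 if ss == 0.0 else np.inf
            p = 1.0 if ss == 0.0 else 0.0
        else:
            f = (ss / df1) / ms_err
            p = float(sps.f.sf(f, df1, df2))
        return {"ss": ss, "df1": df1, "df2": df2, "F": f, "p": p}

    ms_subj = ss_subj / df_subj if df_subj > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    table = pd.DataFrame(
        {
            "group": _row(ss_group, 1, df_subj, ms_subj),
            "population": _row(ss_cond, 1, df_err, ms_err),
            "interaction": _row(ss_inter, 1, df_err, ms_err),
        }
    ).T
    table[["df1", "df2"]] = table[["df1", "df2"]].astype(int)
    return table


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini–Hochberg step-up FDR correction.

    Returns ``(adjusted, reject)`` arrays in input order; adjusted
    p-values are min over j ≥ i of m·p(j)/j, capped at 1, so they are
    non-decreasing in raw-p rank and rejections form a prefix of the
    sorted list.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DegenerateDataError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def ols_regress(x, y) -> RegressionResult:
    """Ordinary least-squares line fit with a two-tailed t-test on the slope."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise DegenerateDataError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("constant predictor")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
    )
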