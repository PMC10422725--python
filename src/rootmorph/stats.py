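"""Cohort statistics for longitudinal root-resorption studies.

Distribution checks (Shapiro-Wilk, Levene), one-way ANOVA across tooth
classes with Bonferroni-adjusted pairwise post-hocs, unpaired Student
t-tests between treatment groups, chi-square for categorical balance,
multiple linear regression of resorption on expander type and expansion
amounts, two-way random-effects ICC for rater reliability, and the
noncentral-t sample-size computation for a two-group mean comparison.

Group comparisons default to the pooled-variance Student t-test (the
design assumes homogeneous variance, checked beforehand with Levene);
Welch is available by flag. The observation unit is the tooth; no
clustering correction for teeth within patients is applied — a
documented limitation of this analysis layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .mesh_core import ValidationError

__all__ = [
    "RegressionResult",
    "IccResult",
    "normality_and_variance",
    "anova_bonferroni",
    "two_sample_t",
    "side_pooling_pretest",
    "chi_square_counts",
    "err_regression",
    "icc",
    "sample_size_two_means",
]


def _groups(table: pd.DataFrame, variable: str, grouping: str) -> dict:
    if variable not in table or grouping not in table:
        raise ValidationError(f"table lacks column {variable!r} or {grouping!r}")
    return {
        k: np.asarray(v[variable], dtype=float)
        for k, v in table.groupby(grouping, observed=True)
    }


def normality_and_variance(
    table: pd.DataFrame, variable: str, grouping: str
) -> pd.DataFrame:
    """Per-group Shapiro-Wilk plus a shared Levene test (mean-centred).

    Returns one row per group with columns ``shapiro_w``, ``shapiro_p``,
    ``levene_stat``, ``levene_p`` (the Levene values repeat across rows).
    Groups with (near-)zero variance are flagged in ``degenerate``.
    """
    groups = _groups(table, variable, grouping)
    if any(len(v) < 3 for v in groups.values()):
        raise ValidationError("need at least 3 observations per group")
    degenerate = {k: bool(np.ptp(v) < 1e-12) for k, v in groups.items()}
    if all(degenerate.values()):
        raise ValidationError("all groups are constant; variance tests undefined")
    lev_stat, lev_p = sps.levene(*groups.values(), center="mean")
    rows = []
    for k, v in groups.items():
        if degenerate[k]:
            w, p = float("nan"), float("nan")
        else:
            w, p = sps.shapiro(v)
        rows.append(
            {
                "group": k,
                "n": len(v),
                "shapiro_w": w,
                "shapiro_p": p,
                "levene_stat": float(lev_stat),
                "levene_p": float(lev_p),
                "degenerate": degenerate[k],
            }
        )
    return pd.DataFrame(rows)


def anova_bonferroni(
    table: pd.DataFrame, variable: str, factor: str
) -> dict:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Student t-tests.

    The adjusted p is the raw pairwise p multiplied by the number of
    pairs, clamped at 1.
    """
    groups = _groups(table, variable, factor)
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two factor levels")
    if any(len(v) < 2 for v in groups.values()):
        raise ValidationError("each level needs at least 2 observations")
    f_stat, p = sps.f_oneway(*groups.values())
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        t, p_raw = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(p_raw * len(pairs), 1.0)),
            }
        )
    return {"F": float(f_stat), "p": float(p), "pairwise": pd.DataFrame(rows)}


def two_sample_t(
    table: pd.DataFrame,
    variable: str,
    grouping: str,
    welch: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Unpaired two-group t-test with mean difference and CI.

    Pooled-variance Student by default; Welch with ``welch=True``.
    """
    groups = _groups(table, variable, grouping)
    if len(groups) != 2:
        raise ValidationError(f"grouping {grouping!r} must have exactly 2 levels")
    (ka, a), (kb, b) = sorted(groups.items())
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 observations per group")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    diff = float(a.mean() - b.mean())
    if welch:
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        df = se**4 / (
            (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
            + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
        )
    else:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return {
        "groups": (ka, kb),
        "t": float(t),
        "df": float(df),
        "p": float(p),
        "mean_diff": diff,
        "ci": (diff - tcrit * se, diff + tcrit * se),
    }


def side_pooling_pretest(
    table: pd.DataFrame, variable: str, side_col: str = "side"
) -> dict:
    """Right-vs-left equivalence pre-test run before pooling sides.

    Returns the t-test result plus ``poolable`` (p above alpha=0.05).
    The caller should log this before collapsing the side factor.
    """
    res = two_sample_t(table, variable, side_col)
    res["poolable"] = bool(res["p"] > 0.05)
    return res


def chi_square_counts(counts, correction: bool = False) -> dict:
    """Pearson chi-square on a contingency table (2x2 by default use).

    Continuity correction off by default.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal in the contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=correction)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


@dataclass
class RegressionResult:
    """OLS summary in the layout of a standard regression table."""

    outcome: str
    predictors: list
    coef: pd.DataFrame  # B, se, beta, t, p, ci_low, ci_high per predictor
    r_squared: float
    n: int


def err_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors: list,
) -> RegressionResult:
    """OLS of resorption on expander type and expansion amounts.

    Fits ``outcome ~ const + predictors`` by ordinary least squares and
    reports unstandardized B with SE and 95% CI, standardized beta
    (B scaled by sd(x)/sd(y)), t and p, plus the model R-squared.
    """
    y = np.asarray(table[outcome], dtype=float)
    x = table[list(predictors)].astype(float)
    if len(y) <= len(predictors) + 1:
        raise ValidationError("not enough observations for the design")
    design = sm.add_constant(x.to_numpy())
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify an aliased column by rank-drop on removal
        for j, name in enumerate(predictors):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValidationError(f"predictor {name!r} is collinear with the rest")
        raise ValidationError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    sy = y.std(ddof=1)
    rows = []
    for j, name in enumerate(["const", *predictors]):
        beta = float("nan")
        if name != "const":
            beta = fit.params[j] * x[name].std(ddof=1) / sy
        rows.append(
            {
                "predictor": name,
                "B": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "beta": float(beta),
                "t": float(fit.tvalues[j]),
                "p": float(fit.pvalues[j]),
                "ci_low": float(ci[j][0]),
                "ci_high": float(ci[j][1]),
            }
        )
    return RegressionResult(
        outcome=outcome,
        predictors=list(predictors),
        coef=pd.DataFrame(rows),
        r_squared=float(fit.rsquared),
        n=len(y),
    )


@dataclass
class IccResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def icc(ratings: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (subjects x raters/sessions), complete. Computed from
    the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2D subjects-by-raters table")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValidationError("need at least 5 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValidationError("ratings table has missing cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise ValidationError("degenerate ratings; ICC undefined")
    return IccResult(
        icc=float((msr - mse) / denom),
        model="two-way random, absolute agreement, single measurement (2,1)",
        n_subjects=n,
        n_raters=k,
    )


def _t_power(n: int, delta: float, sd_pooled: float, alpha: float) -> float:
    """Power of a two-sided pooled t-test at n per group (noncentral t)."""
    df = 2 * n - 2
    nc = delta / (sd_pooled * np.sqrt(2.0 / n))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_means(
    mean_diff: float,
    sd1: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 100000,
) -> int:
    """Smallest n per group for a two-sided pooled t-test to reach power.

    SDs of the two groups are pooled as sqrt((sd1^2 + sd2^2)/2); power is
    evaluated with the noncentral-t distribution.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("SDs must be positive")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValidationError("alpha and power must lie in (0, 1)")
    if mean_diff == 0:
        raise ValidationError("zero mean difference can never be detected")
    sd_pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    for n in range(2, n_max + 1):
        if _t_power(n, abs(mean_diff), sd_pooled, alpha) >= power:
            return n
    raise ValidationError(f"required n exceeds {n_max} per group")
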