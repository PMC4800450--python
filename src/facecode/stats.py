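"""Inferential battery for individual-differences brain-behavior analyses.

Four operations cover the statistics used downstream: Pearson correlation
with its t-based p-value, the Meng–Rosenthal–Rubin Z test for comparing two
dependent correlations that share one variable, OLS multiple regression with
standardized coefficients, and a pooled-variance two-group t test with
Cohen's d.

Correlation and regression p-values are two-tailed; the dependent-correlation
comparison is one-tailed, matching the directional question it answers
("is r12 larger than r13?"). No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "CorrelationResult",
    "DependentCorrComparison",
    "RegressionRow",
    "pearson_with_p",
    "steiger_z",
    "ols_regression",
    "two_group_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its two-tailed p-value.

    p is derived from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees
    of freedom.
    """

    r: float
    p_two_tailed: float
    n: int


@dataclass(frozen=True)
class DependentCorrComparison:
    """Comparison of two dependent correlations sharing variable 1.

    r12 and r13 are the two correlations being compared; r23 is the
    correlation between the two non-shared variables. Z follows the
    Meng–Rosenthal–Rubin form; p_one_tailed is the upper-tail normal
    probability of Z (small when r12 > r13).
    """

    r12: float
    r13: float
    r23: float
    n: int
    z: float
    p_one_tailed: float


@dataclass(frozen=True)
class RegressionRow:
    predictor: str
    beta: float
    se_beta: float
    standardized_beta: float
    p: float


def _as_1d(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson correlation of two equal-length vectors with two-tailed p.

    Raises ValueError for mismatched lengths, n < 3, or a constant input
    (the correlation is undefined when either variable has zero variance).
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined for zero-variance data")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_tailed=float(res.pvalue), n=n)


def steiger_z(r12: float, r13: float, r23: float, n: int) -> DependentCorrComparison:
    """Test the difference of two dependent correlations sharing variable 1.

    Uses the Meng–Rosenthal–Rubin statistic: Fisher-transform r12 and r13,
    then

        Z = (z12 - z13) * sqrt((n - 3) / (2 * (1 - r23) * h))

    with rbar^2 = (r12^2 + r13^2) / 2, f = min(1, (1 - r23) / (2 * (1 - rbar^2)))
    and h = (1 - f * rbar^2) / (1 - rbar^2). The returned p is one-tailed
    (upper tail), so it is small when r12 exceeds r13.

    Swapping r12 and r13 exactly negates Z.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < float(r) < 1.0:
            raise ValueError(
                f"{name}={r} must lie strictly inside (-1, 1); the Fisher transform "
                "diverges at |r| = 1"
            )
    n = int(n)
    if n < 4:
        raise ValueError(f"n={n}: need n >= 4")

    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar_sq = (r12 ** 2 + r13 ** 2) / 2.0
    f = min(1.0, (1.0 - r23) / (2.0 * (1.0 - rbar_sq)))
    h = (1.0 - f * rbar_sq) / (1.0 - rbar_sq)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    p = float(sps.norm.sf(z))
    return DependentCorrComparison(
        r12=float(r12), r13=float(r13), r23=float(r23), n=n,
        z=float(z), p_one_tailed=p,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # columns loading on near-null singular vectors
    _, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    bad: set[str] = set()
    for i, sv in enumerate(s):
        if sv <= tol * 1e3 or sv < 1e-10 * s.max():
            load = np.abs(vt[i])
            for j in np.nonzero(load > 0.1)[0]:
                bad.add(names[j])
    return sorted(bad)


def ols_regression(response, predictors: pd.DataFrame) -> pd.DataFrame:
    """Multiple OLS regression with standardized coefficients.

    Parameters
    ----------
    response : 1-d array-like
    predictors : DataFrame of named predictor columns (no intercept column;
        one is added automatically).

    Returns
    -------
    DataFrame with one row per predictor plus the intercept; columns
    ``predictor, beta, se_beta, standardized_beta, p``. The standardized
    coefficient is beta * sd(x) / sd(y); it is NaN for the intercept.
    """
    y = _as_1d(response, "response")
    if not isinstance(predictors, pd.DataFrame):
        raise TypeError("predictors must be a pandas DataFrame with named columns")
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    if X.shape[0] != y.size:
        raise ValueError(f"length mismatch: response {y.size}, predictors {X.shape[0]}")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            "collinear predictors: " + ", ".join(_collinear_columns(X, names) or names)
        )
    fit = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    rows = []
    for i, name in enumerate(["intercept"] + names):
        beta = float(fit.params[i])
        std_beta = np.nan
        if i > 0:
            std_beta = beta * X[:, i - 1].std(ddof=1) / sd_y
        rows.append(
            {
                "predictor": name,
                "beta": beta,
                "se_beta": float(fit.bse[i]),
                "standardized_beta": std_beta,
                "p": float(fit.pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoGroupResult:
    t: float
    p_two_tailed: float
    cohens_d: float
    n0: int
    n1: int


def two_group_test(scores, group) -> TwoGroupResult:
    """Pooled-variance two-sample t test with Cohen's d.

    ``group`` is a binary vector; d = (mean1 - mean0) / pooled SD, so the
    sign follows group 1 minus group 0.
    """
    scores = _as_1d(scores, "scores")
    g = np.asarray(group)
    if g.shape != scores.shape:
        raise ValueError("scores and group must have equal length")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"group must be binary, found levels {levels}")
    a = scores[g == levels[1]]
    b = scores[g == levels[0]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 members")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    sp = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    d = (a.mean() - b.mean()) / sp
    return TwoGroupResult(t=float(t), p_two_tailed=float(p), cohens_d=float(d),
                          n0=int(b.size), n1=int(a.size))


def identification_rate(n_identified: int, n_total: int) -> int:
    """Percentage of subjects in whom an ROI was identified, rounded to an integer."""
    if not 0 <= n_identified <= n_total or n_total <= 0:
        raise ValueError("require 0 <= n_identified <= n_total and n_total > 0")
    return int(round(100.0 * n_identified / n_total))
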