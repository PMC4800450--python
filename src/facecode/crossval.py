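"""Balanced fourfold cross-validated prediction with a permutation null.

The predictive statistic is r(prediction, observation): subjects are split
into k near-equal folds, a simple linear regression of y on x is fitted on
the complementary folds and used to predict each held-out fold, and the
Pearson correlation between the concatenated out-of-fold predictions and
the observed y summarizes predictability.

Folds are "balanced": a random partition is accepted only when a k-sample
Kruskal–Wallis test finds no significant distributional difference across
folds for either variable.

Significance comes from a permutation null: the predictor x is shuffled B
times, the full cross-validated statistic is recomputed for each shuffle
with the folds held fixed, and p is one minus the percentile of the true
statistic in the null — implemented literally as
(number of null values >= true) / B, which can be exactly 0; the smoothed
estimator (count + 1) / (B + 1) is available and is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats as sps

__all__ = ["FoldAssignment", "CVResult", "balanced_folds", "cv_predict",
           "permutation_p"]


@dataclass(frozen=True)
class FoldAssignment:
    """Per-subject fold labels in {1..k} with the recorded balance evidence."""

    folds: np.ndarray
    k: int
    balance_test: str
    p_x: float
    p_y: float
    seed: int | None
    restarts_used: int


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold predictions and their agreement with the observations."""

    predictions: np.ndarray
    r_prediction_observation: float
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be equal-length 1-d vectors")
    return x, y


def balanced_folds(
    x,
    y,
    k: int = 4,
    balance_alpha: float = 0.05,
    max_restarts: int = 1000,
    seed: int | None = None,
) -> FoldAssignment:
    """Random k-way partition accepted only when both variables are balanced.

    Partitions are drawn by shuffling subjects into folds whose sizes differ
    by at most one. Each candidate is tested with a Kruskal–Wallis k-sample
    test applied separately to x and to y across folds; the first candidate
    with both p-values above ``balance_alpha`` is returned. Deterministic
    given ``seed``.
    """
    x, y = _check_xy(x, y)
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for k={k} folds")
    rng = np.random.default_rng(seed)
    base = np.arange(n) % k + 1  # sizes differ by at most 1
    best = (-np.inf, None, None)
    for attempt in range(1, max_restarts + 1):
        folds = base[rng.permutation(n)]
        p_x = sps.kruskal(*(x[folds == f] for f in range(1, k + 1))).pvalue
        p_y = sps.kruskal(*(y[folds == f] for f in range(1, k + 1))).pvalue
        if p_x > balance_alpha and p_y > balance_alpha:
            return FoldAssignment(folds=folds, k=k, balance_test="kruskal-wallis",
                                  p_x=float(p_x), p_y=float(p_y), seed=seed,
                                  restarts_used=attempt)
        if min(p_x, p_y) > best[0]:
            best = (min(p_x, p_y), float(p_x), float(p_y))
    raise RuntimeError(
        f"no balanced partition found in {max_restarts} restarts; best attempt "
        f"had p_x={best[1]:.4g}, p_y={best[2]:.4g} (alpha={balance_alpha})"
    )


def _validate_folds(folds: np.ndarray, k: int, n: int) -> None:
    folds = np.asarray(folds)
    if folds.shape != (n,):
        raise ValueError("fold assignment must cover every subject exactly once")
    if not set(np.unique(folds)) <= set(range(1, k + 1)):
        raise ValueError("fold labels must lie in {1..k}")


def cv_predict(x, y, folds: FoldAssignment) -> CVResult:
    """Leave-fold-out linear prediction of y from x.

    For each fold, slope and intercept are estimated by least squares on
    the other folds and applied to the held-out subjects; the statistic is
    the Pearson correlation of the concatenated predictions with y.
    """
    x, y = _check_xy(x, y)
    _validate_folds(folds.folds, folds.k, x.size)
    preds = np.empty_like(y)
    for f in range(1, folds.k + 1):
        test = folds.folds == f
        train = ~test
        xt, yt = x[train], y[train]
        if np.ptp(xt) == 0:
            raise ValueError(f"constant x in the training set for fold {f}")
        slope, intercept = np.polyfit(xt, yt, 1)
        preds[test] = slope * x[test] + intercept
    r = float(np.corrcoef(preds, y)[0, 1])
    return CVResult(predictions=preds, r_prediction_observation=r)


def _cv_r_rows(xs: np.ndarray, y: np.ndarray, folds: np.ndarray, k: int) -> np.ndarray:
    """r(prediction, observation) for each row of xs (vectorized over rows)."""
    B, n = xs.shape
    preds = np.empty((B, n))
    for f in range(1, k + 1):
        test = folds == f
        train = ~test
        xt = xs[:, train]
        yt = y[train]
        mx = xt.mean(axis=1)
        my = yt.mean()
        dx = xt - mx[:, None]
        var = (dx ** 2).mean(axis=1)
        if np.any(var == 0):
            raise ValueError(f"constant x in the training set for fold {f}")
        slope = (dx * (yt - my)).mean(axis=1) / var
        intercept = my - slope * mx
        preds[:, test] = slope[:, None] * xs[:, test] + intercept[:, None]
    pc = preds - preds.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((pc ** 2).sum(axis=1)) * np.linalg.norm(yc)
    return (pc @ yc) / denom


def permutation_p(
    x,
    y,
    folds: FoldAssignment,
    B: int = 5000,
    seed: int | None = None,
    smoothed: bool = False,
    return_null: bool = False,
):
    """Permutation p-value for r(prediction, observation).

    x is shuffled B times; for every shuffle the full cross-validated
    prediction is recomputed with the same fold assignment, giving a null
    distribution of the statistic. The default p is the literal
    one-minus-percentile rule (count of null >= true) / B; with
    ``smoothed=True`` it is (count + 1) / (B + 1).
    """
    x, y = _check_xy(x, y)
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile")
    _validate_folds(folds.folds, folds.k, x.size)
    true_r = cv_predict(x, y, folds).r_prediction_observation
    rng = np.random.default_rng(seed)
    # all shuffles at once; row b is one permutation of x
    perm = np.argsort(rng.random((B, x.size)), axis=1)
    null_r = _cv_r_rows(x[perm], y, folds.folds, folds.k)
    count = int(np.sum(null_r >= true_r))
    p = (count + 1) / (B + 1) if smoothed else count / B
    if return_null:
        return float(p), null_r
    return float(p)
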