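"""Minimal block-design general linear model.

Each condition is modeled as a boxcar convolved with a single-gamma
hemodynamic response function (HRF); the temporal derivative of each
convolved boxcar can be added, plus an intercept. Per-voxel ordinary
least squares yields betas, residual variance and contrast t statistics;
t is converted to a standard-normal-scale Z by matching the two-sided
p-value through the normal quantile, preserving sign, which is what a
"Z > 2.3 (p < 0.01)" threshold presumes.

The gamma HRF is parameterised by peak time and dispersion (SD), both in
seconds; defaults (6 s peak, 3 s SD) follow the conventional single-gamma
used in block-design analyses. Gamma shape k and scale theta follow from
mean = k*theta and var = k*theta^2 with mean = peak_time here taken as the
distribution mean lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
from scipy.special import gammaln, ndtri_exp

__all__ = ["DesignSpec", "GLMFit", "gamma_hrf", "build_design", "fit_glm", "contrast_z"]


@dataclass(frozen=True)
class DesignSpec:
    """Block design: (condition, onset s, duration s) triples on a TR grid."""

    n_volumes: int
    blocks: tuple[tuple[str, float, float], ...]
    tr: float = 2.0
    hrf_peak: float = 6.0
    hrf_dispersion: float = 3.0
    include_derivatives: bool = True
    conditions: tuple[str, ...] | None = None  # declared order; inferred if None

    def __post_init__(self):
        if self.n_volumes <= 0 or self.tr <= 0:
            raise ValueError("n_volumes and tr must be positive")
        total = self.tr * self.n_volumes
        for cond, onset, dur in self.blocks:
            if not (0 <= onset and onset + dur <= total):
                raise ValueError(
                    f"block {cond!r} [{onset}, {onset + dur}] s outside run [0, {total}] s"
                )
            if dur <= 0:
                raise ValueError(f"block {cond!r} has non-positive duration")
        conds = self.condition_order()
        seen = {c for c, _, _ in self.blocks}
        for c in conds:
            if c not in seen:
                raise ValueError(f"condition {c!r} declared but has no blocks")

    def condition_order(self) -> tuple[str, ...]:
        if self.conditions is not None:
            return tuple(self.conditions)
        order: list[str] = []
        for c, _, _ in self.blocks:
            if c not in order:
                order.append(c)
        return tuple(order)


def gamma_hrf(t: np.ndarray, peak: float = 6.0, dispersion: float = 3.0) -> np.ndarray:
    """Single-gamma HRF sampled at times t (s), unit sum over its support."""
    shape = (peak / dispersion) ** 2
    scale = dispersion ** 2 / peak
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def build_design(spec: DesignSpec, oversample: int = 20) -> tuple[np.ndarray, list[str]]:
    """Design matrix (n_volumes x regressors) and regressor names.

    One convolved-boxcar column per condition, then (optionally) its
    temporal derivative, then a trailing intercept column. Convolution is
    carried out on a grid of ``oversample`` points per TR and sampled at
    volume acquisition times.
    """
    dt = spec.tr / oversample
    n_fine = spec.n_volumes * oversample
    t_hrf = np.arange(0, 32.0 + dt, dt)
    hrf = gamma_hrf(t_hrf, spec.hrf_peak, spec.hrf_dispersion)
    hrf = hrf / hrf.sum()

    conds = spec.condition_order()
    cols: list[np.ndarray] = []
    names: list[str] = []
    sample_idx = np.arange(spec.n_volumes) * oversample
    for cond in conds:
        boxcar = np.zeros(n_fine)
        for c, onset, dur in spec.blocks:
            if c == cond:
                i0 = int(round(onset / dt))
                i1 = int(round((onset + dur) / dt))
                boxcar[i0:i1] = 1.0
        conv = np.convolve(boxcar, hrf)[:n_fine]
        cols.append(conv[sample_idx])
        names.append(cond)
    if spec.include_derivatives:
        for cond, col in zip(conds, list(cols)):
            cols.append(np.gradient(col, spec.tr))
            names.append(f"{cond}_derivative")
    cols.append(np.ones(spec.n_volumes))
    names.append("intercept")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class GLMFit:
    """Per-voxel least-squares fit of a shared design matrix.

    betas has shape (regressors, voxels); residual_variance is the unbiased
    estimate per voxel; df = n_volumes - rank(design).
    """

    betas: np.ndarray
    residual_variance: np.ndarray
    df: int
    design: np.ndarray
    regressor_names: list[str]


def _collinear_sets(X: np.ndarray, names: list[str]) -> list[str]:
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    bad: set[str] = set()
    for i in np.nonzero(s <= tol)[0]:
        for j in np.nonzero(np.abs(vt[i]) > 1e-8)[0]:
            bad.add(names[j])
    return sorted(bad)


def fit_glm(
    timeseries: np.ndarray,
    design: np.ndarray,
    regressor_names: list[str] | None = None,
    nuisance: np.ndarray | None = None,
) -> GLMFit:
    """OLS fit of every voxel's time course against a shared design.

    timeseries is (voxels, time); design is (time, regressors); nuisance,
    if given, is (time, covariates) and is appended to the design. The
    returned betas cover design columns first, then nuisance columns.
    """
    Y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    X = np.asarray(design, dtype=float)
    names = list(regressor_names) if regressor_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != X.shape[0]:
            raise ValueError("nuisance rows must match design rows")
        X = np.hstack([X, nuis])
        names += [f"nuisance{i}" for i in range(nuis.shape[1])]
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"time dimension mismatch: data has {Y.shape[1]} volumes, design {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design; collinear columns: "
                         + ", ".join(_collinear_sets(X, names)))
    betas, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ betas
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_res = (resid ** 2).sum(axis=0)
    ss_tot = (Y.T ** 2).sum(axis=0)
    # exact fits leave only rounding noise: snap to zero residual variance
    ss_res[ss_res <= 1e-20 * ss_tot] = 0.0
    rv = ss_res / df
    return GLMFit(betas=betas, residual_variance=rv, df=df, design=X,
                  regressor_names=names)


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    # two-sided p-matching in log space; sign-preserving, inf passes through
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    finite = np.isfinite(t)
    logp = sps.t.logsf(np.abs(t[finite]), df)  # one-sided log p
    z[finite] = -ndtri_exp(logp) * np.sign(t[finite])
    z[~finite] = t[~finite]
    return z


def contrast_z(fit: GLMFit, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contrast t and Z per voxel for a weight vector over the regressors.

    t = (c' beta) / SE(c' beta); Z maps the two-sided t p-value through the
    standard normal quantile, preserving sign. A voxel with zero residual
    variance and a nonzero contrast yields +/-inf (signalled, not raised);
    zero contrast with zero variance yields 0.
    """
    c = np.asarray(weights, dtype=float)
    if c.size != fit.betas.shape[0]:
        raise ValueError(
            f"contrast length {c.size} != number of regressors {fit.betas.shape[0]}"
        )
    eff = c @ fit.betas  # per voxel
    xtx_inv = np.linalg.inv(fit.design.T @ fit.design)
    var_scale = float(c @ xtx_inv @ c)
    se = np.sqrt(var_scale * fit.residual_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / np.where(se > 0, se, 1.0),
                     np.where(eff == 0, 0.0, np.inf * np.sign(eff)))
    z = _t_to_z(t, fit.df)
    return t, z
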