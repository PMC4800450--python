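"""Synthetic cohorts with planted, independently tunable brain-behavior effects.

The generator emulates an individual-differences face-perception study:
each subject contributes (a) behavioral scores — a 36-item expression
recognition score, old/new recognition accuracies for faces and flowers,
and gender — and (b) an ROI "pattern matrix" of per-category, per-run beta
vectors plus a faces-versus-objects contrast Z vector.

Two latent channels drive the brain-behavior structure and are statistically
independent of each other, so the simulated double dissociation is
structural:

* an *amplitude* latent sets each subject's mean contrast Z (univariate
  selectivity) and is correlated with the expression score at
  ``rho_selectivity_expression``;
* a *separation* latent sets the angle between the subject's face and
  object spatial patterns (hence the between-category dissimilarity) and
  is correlated with the face-recognition accuracy at
  ``rho_dissim_identity``.

Pattern geometry. For each subject an orthonormal, zero-mean basis
e1..eK is drawn in voxel space (K = number of categories). The object
pattern is e1; the face pattern is cos(theta) e1 + sin(theta) e2 with the
angle chosen so that the mean-pattern-centered correlation of the noiseless
face and object patterns equals 1 minus the subject's target separation;
remaining categories use e3, e4, ... This makes the measured dissimilarity
analytically controllable. Because run noise both shrinks and jitters a
pattern correlation, behavioral scores are calibrated against the
*expected measured* dissimilarity (a fixed monotone function of the latent
separation that accounts for the known noise shrinkage), so the planted
population correlation refers to the quantity the measurement pipeline
actually computes.

Scores are linear-Gaussian in the latents, then clipped to their valid
ranges (expression additionally rounded to an integer); clipping rates are
recorded on the returned truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glm import DesignSpec, build_design
from .roi import DEFAULT_CATEGORIES, PatternMatrix

__all__ = [
    "SimConfig",
    "CohortTruth",
    "generate_cohort",
    "generate_bold",
    "default_design_spec",
    "expected_measured_dissimilarity",
]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions the generator emulates: a
    165-subject analyzed cohort, planted correlations 0.22 (selectivity ->
    expression) and 0.27 (pattern separation -> identity accuracy), a
    standardized female advantage of 0.58 on the expression score, three
    runs over four stimulus categories, and a 200-voxel ROI.
    """

    n_subjects: int = 165
    n_voxels: int = 200
    n_runs: int = 3
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    rho_selectivity_expression: float = 0.22
    rho_dissim_identity: float = 0.27
    rho_behavior_cross: float = 0.0
    gender_effect_d: float = 0.58
    female_fraction: float = 0.6
    noise_sd: float = 0.5
    pattern_sd: float = 1.0
    # latent population parameters (Z units for amplitude; dissimilarity
    # units for separation, clipped to the geometrically reachable range)
    amplitude_mean: float = 3.5
    amplitude_sd: float = 1.0
    separation_mean: float = 1.0
    separation_sd: float = 0.30
    separation_bounds: tuple[float, float] = (0.05, 1.75)
    z_voxel_sd: float = 1.0
    eyes_mean: float = 24.0
    eyes_sd: float = 3.0
    face_acc_mean: float = 0.78
    face_acc_sd: float = 0.09
    flower_acc_mean: float = 0.81
    flower_acc_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (within-category reliability "
                             "needs two runs)")
        if len(self.categories) < 3:
            raise ValueError("need >= 3 categories for mean-pattern removal")
        for lab in ("faces", "objects"):
            if lab not in self.categories:
                raise ValueError(f"categories must include {lab!r}")
        if self.n_voxels < len(self.categories) + 1:
            raise ValueError("n_voxels must exceed the number of categories")
        for name in ("rho_selectivity_expression", "rho_dissim_identity",
                     "rho_behavior_cross"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly inside (-1, 1)")
        if self.noise_sd <= 0 or self.pattern_sd <= 0:
            raise ValueError("noise_sd and pattern_sd must be positive")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must lie in (0, 1)")
        lo, hi = self.separation_bounds
        if not 0.0 <= lo < hi <= 16.0 / 9.0:
            raise ValueError("separation_bounds must lie within [0, 16/9], the "
                             "range reachable by the centered pattern geometry")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth behind a generated cohort (for tests and calibration)."""

    amplitude: np.ndarray          # latent mean contrast Z per subject
    separation: np.ndarray         # target noiseless centered dissimilarity
    expected_dissim: np.ndarray    # E[measured dissimilarity | separation]
    gender: np.ndarray             # 1 = female, 0 = male
    eyes_mean: float
    face_acc_mean: float
    clip_rates: dict[str, float] = field(default_factory=dict)


def _centered_corr_from_angle_cos(c: np.ndarray, k: int) -> np.ndarray:
    """Centered face/object pattern correlation given raw cosine c (K cats)."""
    num = c - 2.0 * (1.0 + c) / k + (k + 2.0 * c) / k ** 2
    den = 1.0 - 2.0 * (1.0 + c) / k + (k + 2.0 * c) / k ** 2
    return num / den


def _angle_cos_for_target(t: np.ndarray, k: int) -> np.ndarray:
    """Invert the centered correlation: cosine giving centered corr t."""
    # centered corr is a Mobius map of c: t = (c*p1 + q1) / (c*p2 + q2)
    p1 = 1.0 - 2.0 / k + 2.0 / k ** 2
    q1 = 1.0 / k - 2.0 / k
    p2 = -2.0 / k + 2.0 / k ** 2
    q2 = 1.0 - 2.0 / k + 1.0 / k
    return (t * q2 - q1) / (p1 - t * p2)


def expected_measured_dissimilarity(
    separation: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Expected dissimilarity the roi module measures, given the latent target.

    Accounts for the shrinkage of a pattern correlation by run-averaged
    voxel noise (variance noise_sd^2 / n_runs per voxel, reduced by the
    mean-pattern centering to a (1 - 1/K) share, with a -1/K cross-category
    covariance share in the numerator).
    """
    k = len(config.categories)
    t = 1.0 - np.asarray(separation, dtype=float)
    c = _angle_cos_for_target(t, k)
    sr2 = config.noise_sd ** 2 / config.n_runs
    g2 = config.pattern_sd ** 2
    num = g2 * (
        c - 2.0 * (1.0 + c) / k + (k + 2.0 * c) / k ** 2
    ) - sr2 / k
    den = g2 * (
        1.0 - 2.0 * (1.0 + c) / k + (k + 2.0 * c) / k ** 2
    ) + sr2 * (1.0 - 1.0 / k)
    return 1.0 - num / den


def _hermgauss_moments(f, mean, sd, lo, hi, n_nodes: int = 201):
    """E[f(clip(mean + sd*Z, lo, hi))] and its second moment, Z ~ N(0,1)."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    s = np.clip(mean + sd * x, lo, hi)
    v = f(s)
    m1 = float(np.sum(w * v))
    m2 = float(np.sum(w * v ** 2))
    return m1, np.sqrt(max(m2 - m1 ** 2, 1e-300))


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[PatternMatrix], CohortTruth]:
    """Generate one cohort: subject table, per-subject patterns, ground truth.

    Deterministic given ``config.seed``. The subject table has columns
    subject_id, gender, eyes_score, face_acc, flower_acc.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = len(config.categories)
    v = config.n_voxels

    # --- latents ------------------------------------------------------
    z_amp = rng.standard_normal(n)
    z_sep = rng.standard_normal(n)
    gender = (rng.random(n) < config.female_fraction).astype(int)
    eps_eyes = rng.standard_normal(n)
    eps_face = rng.standard_normal(n)
    eps_flower = rng.standard_normal(n)
    if config.rho_behavior_cross != 0.0:
        rb = config.rho_behavior_cross
        eps_face = rb * eps_eyes + np.sqrt(1.0 - rb ** 2) * eps_face

    amplitude = config.amplitude_mean + config.amplitude_sd * z_amp
    lo, hi = config.separation_bounds
    separation_raw = config.separation_mean + config.separation_sd * z_sep
    separation = np.clip(separation_raw, lo, hi)
    expected_dissim = expected_measured_dissimilarity(separation, config)

    # standardize the identity channel against the population distribution
    # of the expected measured dissimilarity (Gauss-Hermite over the clipped
    # latent), so the planted correlation targets the measured quantity
    m_d, sd_d = _hermgauss_moments(
        lambda s: expected_measured_dissimilarity(s, config),
        config.separation_mean, config.separation_sd, lo, hi,
    )
    w_ident = (expected_dissim - m_d) / sd_d

    # --- behavioral scores -------------------------------------------
    pq = config.female_fraction * (1.0 - config.female_fraction)
    d = config.gender_effect_d
    rho_e = config.rho_selectivity_expression
    shrink = 1.0 + d ** 2 * pq
    c_e_sq = 1.0 / shrink - rho_e ** 2
    if c_e_sq <= 0:
        raise ValueError("rho_selectivity_expression too large for the "
                         "requested gender effect")
    c_g = d / np.sqrt(shrink)
    eyes_latent = (
        rho_e * z_amp
        + c_g * (gender - config.female_fraction)
        + np.sqrt(c_e_sq) * eps_eyes
    )
    eyes_raw = config.eyes_mean + config.eyes_sd * eyes_latent
    eyes = np.clip(np.rint(eyes_raw), 0, 36).astype(int)

    rho_i = config.rho_dissim_identity
    face_raw = config.face_acc_mean + config.face_acc_sd * (
        rho_i * w_ident + np.sqrt(1.0 - rho_i ** 2) * eps_face
    )
    face_acc = np.clip(face_raw, 0.0, 1.0)
    flower_raw = config.flower_acc_mean + config.flower_acc_sd * eps_flower
    flower_acc = np.clip(flower_raw, 0.0, 1.0)

    clip_rates = {
        "eyes_score": float(np.mean((eyes_raw < 0) | (eyes_raw > 36))),
        "face_acc": float(np.mean((face_raw < 0) | (face_raw > 1))),
        "flower_acc": float(np.mean((flower_raw < 0) | (flower_raw > 1))),
        "separation": float(np.mean((separation_raw < lo) | (separation_raw > hi))),
    }

    # --- pattern matrices --------------------------------------------
    # orthonormal zero-mean basis per subject: QR of [1, gaussians]
    g = rng.standard_normal((n, v, k + 1))
    g[:, :, 0] = 1.0
    q, _ = np.linalg.qr(g)
    basis = q[:, :, 1:]  # (n, v, k) columns orthonormal, zero-mean

    cos_theta = _angle_cos_for_target(1.0 - separation, k)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta ** 2, 0.0, None))

    i_face = config.categories.index("faces")
    i_obj = config.categories.index("objects")
    other = [i for i in range(k) if i not in (i_face, i_obj)]

    scale = config.pattern_sd * np.sqrt(v)
    patterns: list[PatternMatrix] = []
    cat_baseline = np.full(k, 0.5)
    for i in range(n):
        pat = np.zeros((k, v))
        pat[i_obj] = basis[i, :, 0]
        pat[i_face] = cos_theta[i] * basis[i, :, 0] + sin_theta[i] * basis[i, :, 1]
        for j, ic in enumerate(other):
            pat[ic] = basis[i, :, 2 + j]
        means = cat_baseline.copy()
        means[i_face] = 0.5 + 0.3 * amplitude[i]
        noise = config.noise_sd * rng.standard_normal((k, config.n_runs, v))
        betas = means[:, None, None] + scale * pat[:, None, :] + noise
        contrast_z = amplitude[i] + config.z_voxel_sd * rng.standard_normal(v)
        patterns.append(
            PatternMatrix(categories=config.categories, betas=betas,
                          contrast_z=contrast_z)
        )

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "gender": gender,
            "eyes_score": eyes,
            "face_acc": face_acc,
            "flower_acc": flower_acc,
        }
    )
    truth = CohortTruth(
        amplitude=amplitude,
        separation=separation,
        expected_dissim=expected_dissim,
        gender=gender,
        eyes_mean=config.eyes_mean,
        face_acc_mean=config.face_acc_mean,
        clip_rates=clip_rates,
    )
    return subjects, patterns, truth


def default_design_spec(
    tr: float = 2.0,
    block_duration: float = 18.0,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
) -> DesignSpec:
    """One run of the emulated block design: 198 s, 11 blocks of 18 s.

    Three fixation blocks (unmodeled baseline) sandwich two groups of four
    stimulus blocks, one per category; category order is reversed in the
    second group.
    """
    onsets_a = block_duration * np.arange(1, 5)
    onsets_b = block_duration * np.arange(6, 10)
    blocks = [
        (c, float(t), block_duration) for c, t in zip(categories, onsets_a)
    ] + [
        (c, float(t), block_duration) for c, t in zip(categories[::-1], onsets_b)
    ]
    n_volumes = int(round(11 * block_duration / tr))
    return DesignSpec(n_volumes=n_volumes, blocks=tuple(blocks), tr=tr,
                      conditions=tuple(categories))


def generate_bold(
    amplitude: float,
    design: DesignSpec,
    grid_shape: tuple[int, int, int] = (16, 16, 12),
    seed: int = 0,
    noise_sd: float = 0.5,
    blob_center: tuple[int, int, int] | None = None,
    blob_radius: float = 3.0,
    object_amplitude: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 4-D BOLD volume with an embedded face-responsive blob.

    Voxels inside a sphere of ``blob_radius`` respond to the face condition
    with ``amplitude`` (and to the object condition with
    ``object_amplitude``); everything is overlaid with i.i.d. Gaussian
    noise of ``noise_sd`` (pass 0 for a noiseless volume). Returns the
    (x, y, z, t) array and the ground-truth boolean blob mask.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s <= 0 for s in grid_shape):
        raise ValueError("grid_shape must be three positive integers")
    if any(s > 32 for s in grid_shape):
        raise ValueError("grid larger than 32^3 not supported by the simulator")
    if blob_center is None:
        blob_center = tuple(s // 2 for s in grid_shape)
    if any(c - blob_radius < 0 or c + blob_radius > s - 1
           for c, s in zip(blob_center, grid_shape)):
        raise ValueError(
            f"grid {grid_shape} too small to contain a radius-{blob_radius} "
            f"blob at {blob_center}"
        )

    X, names = build_design(design)
    col = {name: X[:, i] for i, name in enumerate(names)}
    face_ts = col["faces"]
    obj_ts = col.get("objects", np.zeros(design.n_volumes))

    coords = np.indices(grid_shape)
    dist2 = sum((coords[i] - blob_center[i]) ** 2 for i in range(3))
    mask = dist2 <= blob_radius ** 2

    rng = np.random.default_rng(seed)
    vol = np.zeros(grid_shape + (design.n_volumes,))
    vol[mask] = amplitude * face_ts + object_amplitude * obj_ts
    if noise_sd > 0:
        vol += noise_sd * rng.standard_normal(vol.shape)
    return vol, mask
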