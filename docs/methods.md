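# Methods

This note records the models, parameter choices and numerical decisions
behind `facecode`, and what the synthetic validation does and does not
establish about real data.

## The analysis model

The pipeline treats each subject as contributing one value per neural
measure and one per behavioral score, and works entirely at the
between-subject level. The neural measures are

- overall selectivity: the faces-versus-objects contrast Z averaged over
  ROI voxels;
- between-category dissimilarity: one minus the Pearson correlation of
  the run-averaged face and object beta patterns after voxelwise
  mean-pattern removal over the full category set;
- within-category dissimilarity: one minus the correlation of the face
  patterns from two independent runs (no centering), an inverse
  reliability.

Mean-pattern ("cocktail-blank") removal over *all* scan categories is the
default because centering over only the two compared categories is
algebraically degenerate: with two categories the centered vectors are
exact negatives, so the dissimilarity is 2 for any non-identical input.
The library refuses that configuration rather than silently returning the
forced value. The centering set is configurable (≥ 3 categories) and
recorded in the run manifest.

Both dissimilarities are asserted to lie in [0, 2] on every computed
value; zero-variance pattern vectors raise an error rather than
propagating NaN.

## Statistics

- Pearson p-values use the exact t transform with n − 2 df (two-tailed).
- The dependent-correlation comparison is pinned to the
  Meng–Rosenthal–Rubin form (with the published cap f ≤ 1), one-tailed.
  Steiger's Z\*₂ variant differs negligibly at the n and r values this
  battery operates at, so only the MRR form is exposed; the statistic is
  exactly antisymmetric under swapping the two compared correlations.
- Regressions are ordinary least squares via statsmodels; standardized
  coefficients are β·sd(x)/sd(y). Collinear designs raise an error naming
  the offending columns. Gender is coded female = 1, male = 0, so a
  female advantage appears as a positive coefficient.
- Group contrasts use the pooled-variance two-sample t and Cohen's d with
  the pooled SD.
- No multiple-testing correction is applied anywhere; the battery reports
  raw p-values and leaves correction to the analyst.

## Cross-validated prediction

Balance is enforced by rejection sampling: random near-equal fourfold
partitions are redrawn until a Kruskal–Wallis k-sample test finds no
significant fold-wise difference (α = 0.05) in *either* analyzed
variable, with a restart cap (default 1000) and a deterministic seed. The
Kruskal–Wallis test was chosen as a rank-based, k-sample,
distribution-level criterion; the accepted partition's p-values are
recorded.

Permutation significance shuffles only the predictor, keeping the folds
fixed, and recomputes the full cross-validated statistic per shuffle. The
default p is the literal one-minus-percentile rule (count of null ≥
observed)/B, which can be exactly 0 and is what reported values such as
"p = 0.0002" presume; the smoothed (count + 1)/(B + 1) estimator is
available and recommended when a strictly positive p is needed. The
permutation engine is vectorised over shuffles; tests pin it to an
explicit per-shuffle loop.

A property of the statistic worth knowing: under independence of x and y,
r(prediction, observation) is not centered on zero but slightly negative
(≈ −0.09 at n = 160, k = 4), because sample-mean centering couples each
out-of-fold prediction to the training targets. An independent
implementation (scikit-learn `cross_val_predict`) reproduces the same
bias, and the permutation null shares it, which is exactly why the
permutation test stays calibrated (empirical type-I rate 0.05 ± 0.02 in
the acceptance suite). Interpreting the raw null r as "zero means no
signal" would be wrong; the permutation p is the meaningful quantity.

## GLM

Each condition is a boxcar convolved with a single-gamma HRF
(peak 6 s, dispersion 3 s — conventional single-gamma defaults; both
exposed on `DesignSpec`), sampled at TR after convolution on a 20×
oversampled grid; temporal derivatives (numerical gradient of each
convolved column) and an intercept complete the design. Fits are plain
OLS per voxel — no prewhitening; runs are analysed either concatenated
with run-wise intercepts or per run. Contrast t is converted to a
normal-scale Z by matching the two-sided p through the normal quantile in
log space (`ndtri_exp`), so the conversion is accurate far into the tails;
exact fits are detected (residual sum of squares below 1e−20 of the data
sum of squares snaps to zero) and yield an explicit ±inf statistic rather
than a rounding-noise-driven finite one. The t→Z gap is O(1/df): ≈ 0.037
at df = 200 and |t| = 3, below 0.01 only from df ≈ 1000 — tests assert
those oracle-computed bounds.

ROI extraction thresholds the Z map (default Z > 2.3), labels connected
components (default 26-connectivity, configurable to 6 or 18), and
returns the component containing the seed, or the component of the
nearest supra-threshold voxel within a search radius (default 5 voxels).
"ROI not identified" is a documented `None` outcome, and the pipeline
excludes such subjects listwise, logging each exclusion, so analyzed +
excluded always equals input.

## Synthetic cohorts

The generator is the package's test bed: it emulates a ~165-subject
individual-differences cohort with two *independent* latent channels, so
the double dissociation in simulated data is structural rather than
incidental.

- **Amplitude channel.** A latent N(3.5, 1.0) mean contrast Z per subject
  (a plausible supra-threshold ROI average); the observed Z vector is the
  latent plus unit-SD per-voxel variation, and the expression score is
  correlated with the latent at `rho_selectivity_expression` (default
  0.22).
- **Separation channel.** A latent target dissimilarity N(1.0, 0.30)
  clipped to [0.05, 1.75]. Each subject gets an orthonormal zero-mean
  basis in voxel space (QR of random Gaussians with a constant column);
  the object pattern is e1 and the face pattern is rotated toward e2 by
  the angle whose mean-pattern-centered correlation equals 1 − target.
  With K categories of equal pattern norm the centered correlation is a
  Möbius function of the raw cosine ((10c − 4)/(12 − 6c) at K = 4), which
  is inverted analytically; its range caps the reachable dissimilarity at
  16/9, hence the clip bound.
- **Calibration against the measured quantity.** Run noise both shrinks
  and jitters a pattern correlation, so the identity score is calibrated
  against the *expected measured* dissimilarity — the analytic function
  of the latent that folds in the known noise shrinkage (run-averaged
  noise variance σ²/R per voxel, reduced to a (1 − 1/K) share by the
  centering, with a −1/K cross-share in the numerator). Population
  moments of that function are computed by Gauss–Hermite quadrature over
  the clipped latent. This makes the planted correlation refer to the
  quantity the `roi` module actually computes; the residual attenuation
  from per-subject measurement jitter at 200 voxels is below ~0.01 in
  correlation units.
- **Scores.** Expression: mean 24, SD 3, rounded and clipped to 0–36,
  with a standardized female advantage d = 0.58 (female fraction 0.6)
  folded into the variance budget so the planted brain-behavior
  correlation is unchanged by the gender term. Accuracies: face
  0.78 ± 0.09, flower 0.81 ± 0.08, clipped to [0, 1]. Clipping rates are
  recorded on the truth object (≈ 0 at the defaults). The cross-
  correlation between the two behavioral channels defaults to 0 and is
  configurable (`rho_behavior_cross`).
- **Noise.** Voxel betas get i.i.d. N(0, 0.5²) noise per run against a
  per-voxel pattern SD of 1.0, yielding within-category dissimilarities
  around 0.2 — a reliable but not noiseless ROI.

What the generator does *not* emulate: temporal autocorrelation and
physiological noise spectra, head motion, spatial smoothness of noise,
resampling/smoothing of Z maps, multi-ROI structure, and any nonlinear
latent-score links. Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under a clean linear-
Gaussian world, not that real acquisitions satisfy those assumptions.

The optional BOLD simulator plants a spherical face-responsive blob in a
small grid (≤ 32³) with the subject's amplitude and i.i.d. Gaussian
noise; it exists to exercise the GLM → ROI path (noiseless recovery,
chance-level false positives, exact blob recovery) at toy scale.

## Problem sizes and determinism

Replicate-cohort checks use 200 cohorts of n = 165 (the calibration and
double-dissociation criteria), 200 null replicates at B = 500 for
permutation type-I, and 10,000 null draws for the dependent-correlation
type-I — sizes at which Monte-Carlo error is comfortably inside each
stated tolerance while the full suite runs in well under a minute. Every
random stage takes an explicit seed; the pipeline spawns per-stage seeds
from a single run seed via `numpy` `SeedSequence`, and a repeated run is
byte-identical.

## Known limitations

- The balanced-fold search can exhaust its restarts on adversarial data
  (it then reports the best attempt's p-values); balance is tested
  marginally per variable, not jointly.
- The permutation p with the literal rule is 0 when the observed
  statistic beats every shuffle; use the smoothed variant when a
  strictly positive value is required downstream.
- The MRR comparison assumes bivariate-normal-ish correlations; it is not
  robust to heavy-tailed score distributions.
- ROI extraction operates on voxel grids only (no surface meshes) and
  assumes the seed is approximately known.
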