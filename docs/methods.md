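# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tonguepipe`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Experimental design and design matrix

The block paradigm has three movement conditions (F, H, V), 15 s blocks,
8 per condition in a seeded pseudorandom order constrained so no condition
occurs more than twice in a row. A 15 s rest follows every third movement
block and the final block; all other blocks are separated by 3 s rests.
With a 15 s lead-in the timeline spans 543 s; at TR 1.8 s the 304 retained
volumes cover 547.2 s. The paradigm clock starts at the first *retained*
volume; `BlockParadigm.shifted` converts onsets between the recorded and
retained clocks after the 4-volume discard.

The HRF is a gamma density parameterized by mean lag 6 s, SD 3 s and phase
0 s, i.e. shape k = (lag/sd)² = 4 and scale θ = sd²/lag = 1.5 s, so its
mode is (k−1)θ = 4.5 s. Condition boxcars are convolved at dt = 0.05 s and
sampled at t = i·TR (slice timing is not modelled). Each condition
contributes a primary regressor plus its temporal derivative
(`np.gradient` of the sampled regressor) as a confound; condition columns
are ordered alphabetically (F, H, V) so contrast vectors are stable under
any block randomization. The *expected response* — the reference series of
the temporal filter — is the union of all movement blocks convolved with
the same HRF.

The high-pass filter is a Gaussian-weighted running-line fit (weight SD
sigma = 45 s) subtracted from the series, with the global mean re-added.
It is linear; measured transfer: a 15 s-period sinusoid is passed at an
RMS ratio ≈ 0.999, a 450 s-period sinusoid is suppressed to ≈ 0.16.

## Pre-processing

* **Discard**: the first 4 recorded volumes (signal equilibration).
* **Realignment** is translation-only: the generator injects pure
  translations, so rotations are carried as zeros (the displacement
  formulas remain 6-dof general). Per-volume shifts against the middle
  volume are found by an integer SSD grid search (±2 voxels) with
  per-axis parabolic refinement. Estimation runs on copies smoothed with a
  1-voxel Gaussian — on a sharp-edged head the raw SSD surface is locally
  V-shaped and parabolic interpolation underestimates sub-voxel shifts by
  up to ~50%; smoothing makes the surface quadratic (measured recovery
  error < 0.02 voxel on piecewise-constant schedules). Resampling is
  linear interpolation of the unsmoothed data. This estimator is
  fixture-grade: it is not suitable for real data with rotations.
* **Displacement**: for a parameter difference, translations combine with
  rotational arc lengths on an 80 mm-radius sphere in quadrature. Subjects
  are excluded at mean relative displacement ≥ 1 mm or mean absolute
  displacement ≥ 3 mm.
* **Masking** thresholds the temporal-mean volume at 0.25 of its 98th
  percentile, keeps the largest 6-connected component and fills holes
  (again fixture-grade, not a brain-extraction replacement).
* **Smoothing** is a 5 mm-FWHM Gaussian per volume; **grand-mean
  normalization** rescales the whole 4D set by one factor so the in-mask
  grand mean is 10000 (a common convention; only the single-factor rule is
  essential).

## ICA decomposition

Spatial ICA: the in-mask (V × T) matrix is voxel-demeaned, PCA-whitened to
K dimensions (K = 20 by default) and unmixed by deflationary fixed-point
iteration with the tanh (logcosh) contrast, tolerance 1e-6, ≤500
iterations. Deflation is used instead of the symmetric update because with
K well above the true source dimension the trailing noise subspace is
rotation-degenerate and the symmetric update's global convergence
criterion never settles, at any tolerance. The iteration is run from 4
random initializations and the most non-Gaussian converged solution is
kept (sum of squared logcosh-negentropy deviations) — single-init
deflation lands in local optima that leave weak sources mixed.
Non-convergence of an initialization is retried with fresh seeds (≤5) and
raises if persistent.

Conventions: time courses are scaled to unit sample variance (scale
absorbed into maps); maps are divided by the residual SD of the K-rank
reconstruction (z-like units); each component is oriented so the mean of
its top-1 %-|z| voxels is positive (skewness is defeated by broad map
offsets; a lone-peak rule by single noise voxels); components are ordered
by explained variance. Spatial maps can be thresholded by a two-class
Gaussian mixture fitted by EM (k-means init, ≤200 iterations, tol 1e-6):
voxels are active where the posterior of the higher-mean class exceeds
0.5; a vanishing class weight (<1e-3) or an essentially constant map
yields an empty active set. Note the posterior-0.5 rule is bounded by its
own Bayes-optimal error: at 95 % N(0,1) / 5 % N(4,1) the optimal
sensitivity is 89.7 %.

Fixed K replaces automatic (Bayesian-PCA) model-order selection; K = 20 is
the standard low-dimensional choice for comparison against the canonical
ten-network set.

## Motion-component classification and removal

Four features per component: **HFC**, the frequency (as a fraction of
Nyquist) at which the cumulative periodogram reaches half the total power;
**max RP correlation**, the maximum |Pearson r| between the component time
course and an expanded realignment-parameter set (6 parameters, their
first differences, and ±1-volume shifts — 24 regressors, a reduced version
of the full 72-regressor convention); **edge fraction** and **CSF
fraction**, the shares of Σ|map| on the brain-edge shell (boundary layer
plus one layer inside, and a 1-voxel outer shell — in-mask maps make the
inner shell operative) and in the CSF region. A component is noise if CSF
fraction > 0.10, or HFC > 0.35, or the point (max RP correlation, edge
fraction) lies above the published linear boundary
(−19.9751 + 9.9513·rp + 24.8333·edge > 0); all constants configurable.

Removal is non-aggressive: each voxel is regressed on all K time courses
plus an intercept, and only the flagged columns' fitted contribution is
subtracted, leaving variance shared with retained components untouched.
Flagging everything therefore returns the OLS residual plus intercept, and
non-aggressive removal never removes more variance than aggressive
(noise-only) regression.

## GLM, group level and cluster inference

First level: OLS, then per-voxel AR(1) coefficients from the residuals
(clipped to ±0.95, spatially smoothed at 5-voxel FWHM), the AR(1)
whitening transform applied to data and design, and a per-voxel refit
(dof = T − P). On pure AR(1) noise (coefficient 0.3, T ≈ 300) the
prewhitened rejection rate at |z| > 1.96 is ≈ 0.054 versus ≈ 0.14 without
prewhitening — the reason prewhitening exists. Contrasts give cope = cᵀβ,
varcope = σ²cᵀ(XᵀX)⁻¹c and z via the t→Φ⁻¹ probability transform.

Group level replaces two-stage Bayesian mixed-effects estimation with a
method-of-moments one-sample model: between-subject variance
σ²_b = max(0, s² − mean varcope), inverse-variance weights
1/(varcope + σ²_b), z from the weighted mean at n−1 dof. This is a
documented simplification; it is exactly calibrated when varcopes are
equal.

Cluster inference assumes a Gaussian random field. Smoothness per axis is
estimated from the lag-1 correlation of variance-normalized residuals
(FWHM = √(−2 ln 2 / ln r), clamped at 1 voxel with a warning), resels =
N/∏FWHM. Clusters are 26-connected components of {z > 3.1}; the corrected
p combines the expected-cluster-count (Euler characteristic density) with
the exp(−β s^{2/3}) extent survival function under Poisson clumping;
clusters are kept at p < 0.01. Local maxima (voxels ≥ all 26 neighbours)
are reported per cluster in descending z with lexicographic tie-breaks,
suppressing peaks within 20 mm of an accepted peak, at most 100 overall,
each labelled from the toy anatomical label volume.

Two small-grid caveats, observed with the generator: (a) unmodelled
structured signal (planted network components, absent from the design)
inflates the residual-smoothness estimate — correct GRF behaviour, but on
a 24×24×14 grid the resel count can collapse to ~12 and sink genuine
clusters; (b) at very high SNR the suprathreshold region sprawls far
beyond a planted blob (z has no effect-size floor), which can bridge
bilateral blobs into one cluster. The localization check therefore uses a
single blob whose peak z (~10) is of the same order as peak values
typically reported for this paradigm, with the denoising stage disabled
(it is validated separately, and at probe SNR it absorbs the weak task
signal).

## Spatio-temporal filtering

Temporal: Pearson r between each component time course and the expected
response; two-sided p from the t transform at T−2 dof, ignoring temporal
autocorrelation (a documented caveat — the flags, not the exact p, carry
the inference). Flags: positive if r > 0.4 and p < 0.05, negative if
r < −0.4 and p < 0.05.

Spatial: in-mask Pearson r (zero spatial lag) between each *unthresholded*
z map and each of the ten templates, over the intersection of the
component mask and template mask; r > 0.4 is a match; a network is present
if any component matches it; components may match several templates, and
passing the temporal filter does not exclude a component from the spatial
filter. Correlating mixture-thresholded maps instead is available as a
switch but measurably worse on synthetic subjects (lower sensitivity, more
spurious matches), so raw maps are the default.

## The synthetic generator

`fixturegen` emulates exactly the structure the analysis assumes — and
nothing more. A subject is a bright ellipsoidal head (baseline intensity
100) carrying a sum of planted components (map ⊗ amplitude·time course)
plus stationary AR(1) noise (innovation SD 1.0, lag-1 coefficient 0.3) in
the head, then resampled under injected per-volume translations
(piecewise-constant schedules with spikes; "mild" ≈ 0.03 mm mean relative
displacement, "excessive" ≈ 1.2 mm).

Planted components (all maps have unit peak weight; default amplitudes in
parentheses):

* **task_sensorimotor** (4.0): bilateral lateral blobs; time course built
  to have *exactly* the target correlation (0.7) with the expected
  response by mixing the standardized expected response with an
  orthogonalized band-limited (0.005–0.15 Hz) residual — BOLD-like, not
  white, so its high-frequency content resembles real task components.
* **occipital_anticorrelated** (3.0): posterior blobs, target r −0.6.
* **network_<name>** (3.0): map with *exactly* 0.6 in-mask correlation
  with the named template, built as r·τ + √(1−r²)·g where g is a sparse
  random-blob field orthogonalized against the whole template library
  (a Gaussian-texture g would make the plant spatially Gaussian, which
  spatial ICA provably cannot isolate), shifted/scaled to non-negative
  unit-peak form (affine maps preserve Pearson r). Time course:
  band-limited 0.01–0.1 Hz noise — an assumption; the real time-course
  structure of such networks during a task is unknown.
* **edge_motion** (4.0): the 2-voxel inner shell of the head mask; time
  course follows the signed volume-to-volume displacement (spiky at
  transitions) plus broadband jitter.
* **csf** (3.0): central blob with white-noise time course.

The template library is ten synthetic network maps — sums of ≥2 Gaussian
blobs (σ 1.5 voxels) at greedily farthest-point-sampled centres inside
0.70 of the head semi-axes (away from the brain edge, where motion
artifacts live), with reserved exclusion zones around the task, occipital
and CSF plant sites. Pairwise in-mask correlations are verified < 0.3 at
construction (measured max ≈ 0.14). Users can substitute real template
NIfTI maps via `load_template_library`. A toy label volume (label i at
template i's primary blob) supports peak labelling.

What the generator does **not** emulate: anatomy, physiological
(cardiac/respiratory) noise, rotations, susceptibility or slice-timing
effects, spatially correlated noise beyond the smoothing step, and
scanner drifts other than what the high-pass filter sees from the AR(1)
process. Passing tests on this generator therefore demonstrate the
*mechanics* of the analysis — recovery of exactly the structure each
stage is designed for — not performance on real scanner data.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (cohort subject seeds are
derived from one master seed via `numpy` SeedSequence, kept below 2³¹);
fixed seeds give bit-identical outputs. Default problem sizes — 24×24×14
voxel grid (~2800 in-mask voxels), 308 volumes, K = 20, 10-subject
reliability sweeps — were chosen so the full test suite and the acceptance
script each complete in a few minutes on a single CPU while keeping every
stage's statistical behaviour measurable.

## Known limitations

* Realignment and masking are deliberately minimal (translations only,
  intensity threshold); do not run this pipeline on real data.
* The group-level estimator is method-of-moments, not fully Bayesian.
* GRF cluster p-values use the standard closed-form 3D expressions; on
  grids this small with inflated smoothness they are conservative.
* Detection of a planted network at template correlation 0.6 through the
  full pipeline succeeds in roughly 7–10 of 10 subjects depending on the
  seed set: the recovered component's template correlation is the product
  of the planted 0.6 and the ICA estimation fidelity, which at this SNR
  leaves single subjects near the 0.4 match threshold — mirroring the
  per-subject variability such filters show in practice.
* The temporal filter's p-values ignore autocorrelation, as noted above.
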