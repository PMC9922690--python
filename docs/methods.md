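# Methods

This note documents the models, conventions and numerical choices
behind `qcfmri`, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model and conventions

Volumes are NIfTI-1 via nibabel; intensity scaling
(`scl_slope`/`scl_inter`) is applied on load and `datum` records the
on-disk type. Voxel indices are 0-based; mm coordinates use the RAS+
convention of the affine, and left/posterior/inferior labels such as
`"5L, 49P, 40S"` are converted explicitly. Obliquity is the largest
angle between a voxel axis and its nearest cardinal axis; anatomicals
can be deobliqued on load (rotation part snapped to the nearest
axis-aligned matrix, origin preserved) only behind an explicit flag.

Motion parameters are ordered as three rotations in **degrees** then
three translations in **mm**. The Euclidean-norm motion index mixes
those units as-is — the field's convention, defensible because 1° of
head rotation displaces the cortical surface by roughly 1 mm at a
~57 mm radius. This makes the column order load-bearing and it is
documented wherever motion files are read or written.

## Censoring

A TR whose Enorm exceeds the limit censors **both** TRs of the
transition (Enorm at `t` measures the `t-1 → t` difference, so either
endpoint may be corrupted); a TR whose outlier fraction exceeds its
limit censors that TR alone. Defaults: 0.2 mm (resting) / 0.3 mm
(task) for motion, 0.05 for the outlier fraction. `avg censored
motion` is the Enorm mean over retained TRs; `max censored
displacement` is the largest 6-parameter Euclidean distance between
any two **retained** TRs (the "censored" qualifier; using all TR pairs
is the plausible alternative, and would only ever give a larger
value). Censoring is implemented by row deletion, not zero-weighting,
so the degrees-of-freedom accounting is exactly
`df_remain = retained − rank(X)`.

## Outlier fractions

Each voxel is detrended with the run's Legendre baseline (order
`p = 1 + floor(run_seconds/150)`, as below) fitted under an **L1**
criterion (8 iterations of iteratively reweighted least squares). The
L1 fit matters: a least-squares trend is dragged toward exactly the
bright leading volumes and isolated spikes the detector exists to
find, and on short runs that masked genuine pre-steady-state volumes
entirely. A sample is an outlier when its absolute deviation exceeds
`Q * sqrt(pi/2) * MAD`, `Q` the upper-tail normal quantile at
`0.001/n_vols`; zero-MAD voxels never count.

Pre-steady-state detection flags TRs contiguous from TR 0 (at most
`k_max = 5`) whose outlier fraction exceeds
`max(2 x median of the rest, 0.02)`.

## Regression model

* **Baseline**: per-run Legendre polynomials of order 0..p with
  `p = 1 + floor(run_seconds/150)` — Legendre rather than raw powers
  purely for conditioning.
* **Motion**: the six parameters and (optionally) their first
  differences, per run, **demeaned per run**; a column with no
  variation in its run is dropped rather than left to make the design
  singular (with simulated zero motion all six would otherwise be
  null columns).
* **Stimulus regressors**: per class,
  `r(t) = A * sum_e [boxcar(onset_e, d_e) ⊛ g](t)` with
  `g(tau) = (tau/4)^4 exp(4 - tau)` (peak 1 at tau = 4 s) on a 0.05 s
  grid, sampled at the TR grid. `A` is the single constant
  `1/peak(2 s block)`, so a 2 s block peaks at exactly 1 and longer
  events produce proportionally larger responses — the
  duration-modulated convention. Events extending past the run end are
  truncated with a warning.
* **Fit**: censored-row OLS per voxel; contrast t from the coefficient
  covariance; the full-F map is the partial F of the interest group
  against the baseline+motion reduced model. Zero residual variance
  caps F at 1e6 with a flag instead of producing NaN/inf. Rank
  deficiency after censoring raises an error naming the collinear
  columns. Serial correlation is deliberately ignored (plain OLS); the
  generator's AR(1) noise keeps recovery tests honest about that.

Scaling maps each voxel with positive temporal mean to mean 100
(percent-change units), capped at 200; the brain mask (threshold at
50% of the 90th percentile of nonzero mean intensities, largest
connected component, hole-filled) is used for statistics only — maps
are computed and displayed over the full FOV so artifacts outside the
brain stay visible.

## Alignment costs and the flip check

Costs (lower always better): `ls` mean squared difference; `nmi`
negated normalized mutual information from a 32x32 joint histogram;
`lpc`/`lpa` (absolute) local Pearson correlation over non-overlapping
**cubes** of edge 5 resampled voxels (blocks with <10 in-mask voxels
skipped, weights = voxel counts). Cubic blocks are a deliberate
simplification of more elaborate space-filling block shapes; the
local-correlation principle is identical and the edge is configurable.
No hybrid finishing pass is applied on top of `lpc`.

Registration is fully deterministic: multi-resolution (x4, x2, x1 by
default), a coarse grid search over translations at the coarsest level
(default ±10 mm for general registration, ±6 mm inside the flip
check), then Nelder-Mead over all parameters at each level. The
initial simplex uses explicit physical steps (2°, 2 mm x factor, 0.05
scale, 0.02 shear) because the optimizer's default relative simplex
collapses around zero-valued parameters. Non-convergence returns the
best-found transform with a `converged=False` flag; only an exception
counts as failure.

The flip check mirrors the EPI about the grid's mid-sagittal plane (in
mm, after deobliquing), registers both candidates to the anatomical
and compares best costs. Because `lpc` is signed, a multiplicative
margin on raw costs is ill-defined near zero or for negative values;
the margin (default 5%) is therefore applied to the cost **gap**
relative to the larger cost magnitude. Within-margin gaps give
UNCERTAIN with a medium warning; a failed registration on either
branch gives UNCERTAIN with a severe warning. The flip check's
registration budget defaults to 3 levels / 200 simplex iterations per
level — flip decisions degrade quickly with under-converged
registrations, and at phantom sizes this costs ~3 s.

## Review engine

Canonical review keys are verbatim strings (`'censor fraction'`,
`'global correlation (GCOR)'`, ...) so published checklist tables
paste in unchanged. Anything not computed is recorded as an explicit
`MISSING` sentinel — a resting-state run has `'fraction TRs censored'`
missing, never zero. VARY comparisons round floats to 3 decimals
(header jitter at 1e-6 is not a real difference; 0.93 vs 1.0 mm is).
The group standard in the property audit is the mode, ties broken by
first-seen value with the tie itself reported. Manual qualitative
labels enter categorization paired with the rater's severity
("exclusion" or "warning") because a label string does not encode how
bad the finding was; any exclusion-level trigger excludes, else any
warning-level trigger yields uncertain, else include.

Condition numbers are `lambda_max/lambda_min` of `X'X` over
unit-L2-normalized columns of each sub-model (baseline / motion /
interest / baseline+motion / full). Normalizing makes the numbers
comparable across sub-models of different scales; computing on `X'X`
rather than `X` squares the singular-value ratio, and both conventions
exist in the wild — comparisons against numbers produced under the
other convention need a square root. Pairwise-correlation warnings
default to `|r| >= 0.4`, a warning rather than an exclusion since
modest negative correlations between two alternating stimulus classes
are expected and acceptable.

The interstimulus interval is strictly onset separation minus the
preceding duration; rest before the first and after the last event is
reported separately and excluded from ISI statistics. Negative ISIs
(overlapping events) are kept in the statistics and flagged.

## Report rendering

Transparent thresholding: per-pixel alpha `min(1, (|v|/thr)^gamma)`
with `gamma = 2` by default — opaque at and above threshold,
increasingly transparent below, suprathreshold clusters outlined.
Edge overlays use the gradient magnitude of the anatomical thresholded
at its in-mask 90th percentile and skeletonized slice-wise to 1-voxel
lines; edges come from the anatomical only, so bright underlay rims
cannot move them. Grayplot rows are per-voxel z-scored residuals
ordered by correlation with the mask-mean residual. Ratings and
comments live in a sidecar JSON per subject, not in the HTML. The HTML
itself is assembled with stdlib string templating.

## Synthetic generator

The generator emulates: an ellipsoidal head with a ventricle-like
core, smooth intensity texture, a left-lateral bright block **and** an
anterior dark band — the two features together make the phantom
asymmetric in two axes, so no rigid rotation can imitate a left-right
mirror (a nearly AP-symmetric phantom lets a 180° z-rotation defeat
the flip check, a degeneracy real heads do not have); baseline-100 EPI
with Legendre drift, AR(1) noise (rho 0.3 by default, so OLS-based
tests face realistic serial correlation), spherical "network" blobs
sharing latent signals (`latent_sd_for_gcor` inverts the approximate
relation `GCOR ≈ f^2 s^2/(s^2+n^2)` for calibration), task responses
through the same duration-modulated basis as the modeling code,
per-TR rigid resampling by a motion schedule (slow wander + persistent
steps), half-FOV Nyquist ghosts along the phase-encode axis,
multiplicative regional dropout, scaled leading volumes, and
whole-volume left-right flips.

Default conditions: TR 2 s, 150 volumes, 3 mm voxels (20x20x14 grid),
baseline 100, noise sd 2 in percent-signal units (voxelwise tSNR near
50), AR(1) rho 0.3; anatomical 24x24x18 at 2.5 mm. TR, voxel size and
tSNR sit in the ranges typical of 3 T human acquisitions; the grids
are deliberately small so the full pipeline — including registrations
— runs in seconds per subject, and tests use 10–150 volumes per run.

**Not** emulated: k-space physics, EPI distortion and B0 effects,
physiological noise structure, partial-volume anatomy, multi-echo or
surface data. Passing tests therefore demonstrate algorithmic
correctness and detector closure on controlled artifacts, not
performance on real scanner data.

## Degenerate inputs and guards

Zero-variance voxels are excluded from GCOR and get 0 in correlation
maps; zero residual sd gives TSNR 0 (flagged), not inf; an empty
automask, an events file missing required columns, negative onsets,
censor vectors of the wrong length, and rank-deficient designs all
raise typed errors early. All correlation maps are clipped to
[-1, 1] after floating-point roundoff.

## Known limitations

* OLS only; no prewhitening, bandpassing, despiking, slice-timing or
  nonlinear template registration.
* The flip check's UNCERTAIN band uses a fixed relative margin (5%);
  there is no calibrated mapping from cost gap to error probability,
  and warning levels beyond medium/severe are not graded.
* The auditory/other network seed coordinates are configuration
  values; only the posterior-cingulate and visual seeds have built-in
  labels.
* The condition-number convention (X'X of normalized columns) must be
  matched when comparing against externally published ranges.
* `max censored displacement` uses retained TR pairs only (see above).
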