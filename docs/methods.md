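# Methods

`cppfmri` implements the analysis chain of a rodent morphine
conditioned-place-preference (CPP) fMRI study: cue-evoked activity
mapping by a windowed GLM, resting-state and cue-state functional
connectivity (FC) among a 10-region cortico-limbic network, graph
node-strength centrality, CPP behavioural scoring, and a per-pair
regression of connectivity on CPP-delta. Because no raw animal data are
distributed, the package ships a synthetic-data generator whose planted
ground truth exercises every stage.

## Signal model and preprocessing

BOLD runs are 4D NIfTI-1 volumes at TR = 2 s with 0.234 × 0.234 × 0.9 mm
voxels. Two conditioning steps are applied, mirroring the split between
the two analysis paths:

- **Spatial smoothing**: separable Gaussian, default FWHM twice the
  voxel size per axis (σ = FWHM/2.3548 in voxel units), reflect
  boundaries to avoid edge darkening on small rodent fields of view.
  Applied to both paths.
- **Temporal band-pass, 0.01–0.1 Hz**: linear detrend followed by an
  ideal rFFT mask. The mask is a spectral projection, so re-application
  changes the output by <1% RMS; we measured that adding reflective
  padding before the FFT worsened both idempotence (1.2% vs 0.4% RMS)
  and stopband rejection on 300-frame runs, so the filter operates on
  the unpadded detrended series. Applied to the FC path only.

The GLM path is not band-pass filtered by default (a flag enables it):
slow confounds there are handled by nuisance regression — six motion
parameters and the whole-brain mean per subject — which is the more
faithful model for task data whose window regressors themselves live
below 0.1 Hz.

## Windowed GLM

Each 10-min cue block is partitioned into 30-s windows (40 windows for
the default two-block schedule). A window regressor is its half-open
boxcar [onset, onset + 30 s) convolved with a rat-adjusted double-gamma
HRF on a 16× oversampled grid, sampled at frame onsets. The rodent HRF
peaks much earlier than the human canonical form; defaults are peak
1.5 s, undershoot 7.5 s, undershoot ratio 6, kernel 20 s, all
configurable. The response gamma is parametrized with shape
1 + peak/dispersion and scale = dispersion so its mode falls exactly at
the nominal peak time; the kernel is peak-normalized to 1, making a
fitted beta directly the peak evoked amplitude in image units.

Fitting is plain voxelwise OLS with df = frames − rank(X). No AR
prewhitening is applied: temporal autocorrelation inflates the nominal
df, which is a documented limitation; nuisance regression follows the
design above. Multi-subject analysis concatenates runs in time with
**shared window regressors** and **per-subject nuisance + intercept
blocks** (block-diagonal), so a single group beta per window is
estimated while nuisance variance cannot leak across animals.

Contrasts are t = wᵀβ / √(σ̂² wᵀ(XᵀX)⁻¹w) with two-sided p; matched
window differences use w = +1/−1 on the two conditions' same-index
windows (positive = first condition greater). Thresholding is
Benjamini–Hochberg FDR at q = 0.05, applied per contrast (a flag pools
across windows; per-contrast matches reporting activation counts per
window), followed by a cluster-extent minimum of 16 voxels (0.79 mm³ at
the protocol geometry). Cluster connectivity defaults to 6-neighbour
faces, configurable to 18/26; extraction is invariant to axis
permutation at matched connectivity.

## Functional connectivity and group statistics

ROI time series are voxel means over each atlas label, taken from
smoothed, band-passed data. FC is the Pearson correlation of all ROI
pairs, Fisher-z transformed with |r| clipped at 1 − 1e-7; the z diagonal
is NaN and excluded everywhere downstream. Condition comparisons use a
paired t-test per pair (df = n − 1 = 11 for the 12-animal design) with
BH-FDR across the C(k,2) = 45 pairs of that one comparison, not pooled
over comparisons.

Seed maps correlate every brain voxel with a seed ROI's mean
(band-passed) series, z-transformed. Group comparisons are voxelwise
paired t-tests, positive meaning the first condition greater.
Cluster-level correction is a **smoothness-matched Monte-Carlo extent
null**, a deliberate substitute for closed-form Gaussian-random-field
theory: per-axis FWHM is estimated from normalized gradients of the map
(clipped to [1, 8] voxels for stability on small grids), null fields are
simulated at that smoothness, and clusters above the one-tailed
voxel-p = 0.05 threshold are retained only if their extent exceeds the
(1 − 0.05) quantile of the null maximum extent. Crucially, when the map
is a t statistic the null simulates t fields (df + 1 smoothed Gaussian
subject fields reduced to a one-sample t), not standardized Gaussian
fields: at a matched voxel-level rate, low-df t fields cluster more
strongly, and a Gaussian null was measured to inflate the family-wise
error to ≈0.20 at a nominal 0.05 on 12-subject maps, while the
t-matched null controls it. A precomputed null-extent table can be
shared across maps of equal smoothness.

Node strength (the "centrality degree") is the signed sum of a node's z
edges — negative edges subtract, following the literal sum of
connections; an absolute-value mode is available since the convention is
ambiguous. Strengths are computed on z rather than r matrices (flag for
r). Graph export writes BrainNet-style files: a 6-column node file
(x y z colour size label) with colour linearly rescaled from strength
between the least and most central node, and an edge file equal to the z
matrix with |z| < 0.2 zeroed — the threshold is a visualization
convention, not an inferential one. Mean seed FC excludes the seed's own
voxels from the averaging mask.

## Behaviour

CPP-delta = morphine-compartment time at the post-conditioning test
minus at pre-conditioning (both 900-s sessions). The learner rule is
delta > 0 **and** >50% permanence on the morphine side; non-learner is
delta < 0 and <50%. The two rules do not partition all cases (e.g.
delta > 0 with ≤50% permanence), so the complement is an explicit
`ambiguous` class — we refuse to guess. The permanence fraction is
computed over the two conditioning compartments only, excluding the
neutral zone, since the rule concerns permanence in the paired
compartments; this choice is recorded in output metadata. Locomotion
summaries report trace-integrated distance and a mean speed over samples
above a rest threshold (default 2 cm/s, configurable — "rest" is
otherwise undefined). Odour preference for a screening day is
(tᵢ/Σⱼtⱼ)/t_water, invariant to uniform rescaling of odourant times.
The brain–behaviour screen regresses each pair's z on CPP-delta across
animals (simple linear regression; slope, Pearson r, R², two-sided p);
raw p is the primary per-pair readout and BH-adjusted p across the 45
pairs is emitted alongside for rigour.

## Synthetic data: what it emulates, what it does not

- **Resting runs**: every voxel of ROI i receives amplitude × latent
  factor i, with factors multivariate normal under the chosen ROI×ROI
  correlation matrix — population FC is analytically exact. Voxel noise
  is AR(1) (default σ = 1 on a baseline of 100, ρ = 0.3), independent
  across voxels so that smoothing, not the generator, induces spatial
  correlation and FC truth stays exact; a per-voxel random-phase slow
  cosine drift (amplitude 0.5) stands in for scanner drift. Defaults:
  300 frames at TR 2 s = one 10-min acquisition; signal amplitude 1.5
  (≈1.5% signal change) — the study reports no cue effect sizes, so
  amplitudes are package conventions.
- **Cue runs**: per-ROI, per-window betas multiply the same
  boxcar∗HRF regressors the GLM builds (shared construction code), so
  noiseless recovery is exact by design and noisy recovery is a fair
  estimator test. The default schedule is two 600-s blocks separated by
  a 300-s interval whose frames carry baseline + noise only (modelled
  downstream by nuisance + intercept).
- **Behaviour**: each animal's latent learner flag is
  Bernoulli(learner fraction, default 7/12). Learners draw
  pre-permanence from U(0.42, 0.52) and post from U(0.55, 0.85);
  non-learners the reverse — ranges chosen so planted classes always
  satisfy their rule, making saturated-effect classification exact.
  Compartment times sum exactly to the 900-s session minus a drawn
  neutral-zone time (N(150, 30²) s, clipped).
- **FC–behaviour coupling**: per-animal covariances set the coupled
  pair's population z to intercept + slope·delta, back-transformed and
  clipped to |r| ≤ 0.99 (logged); matrices are repaired to the nearest
  PSD correlation matrix by eigenvalue clipping when needed (logged).

Not emulated: realignment-scale head motion (runs are generated
aligned; motion tables are small random walks for regression only),
physiological cycles, spatial noise correlation, susceptibility
artefacts, and anatomical realism of ROI shapes (spheres on a
32×32×16 desk-scale grid at the true voxel geometry, not the 128×128×16
acquisition matrix). Passing tests therefore validate the estimators
and error-rate control under the stated noise model, not robustness to
those real-data effects.

Determinism: every generator takes a seed; identical arguments and seed
give bit-identical output. Cohorts derive per-subject streams from one
seed by fixed offsets, and the pipeline's provenance log (config, seed,
versions) suffices to reproduce a bundle byte-for-byte.

## Numerical choices and degenerate inputs

- r clipped to 1 − 1e-7 before atanh; z diagonal NaN and excluded.
- Paired tests with zero-variance differences report t = 0, p = 1.
- Rank-deficient designs fail loudly, naming the collinear columns via
  QR pivot diagnostics; empty masks, empty manifests, 3D files,
  non-positive TR, misaligned windows and non-PSD covariances all raise
  named errors rather than propagating NaNs.
- TR is read from the NIfTI header; an explicit override wins with a
  logged warning (rodent headers are often wrong).
- Simulation sizes for validation suites (null false-positive control
  over 24 seeds, cluster FWE over 40 replicates sharing a 200-field
  null table, slope-sign recovery over 50 cohorts of 12 animals at 150
  frames on a 20×20×10 grid) are the package's desk-scale defaults,
  chosen to give stable error-rate estimates at interactive runtimes.

## Known limitations

OLS without prewhitening overstates df under temporal autocorrelation;
the Monte-Carlo cluster null assumes stationary smoothness; the
generator's spherical ROIs and white spatial noise are idealizations;
and the ambiguous behavioural class means cohort learner counts need
not partition into learners and non-learners on real data.
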