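# Methods

This note documents the models, parameter choices and numerical decisions
behind `seedconn`, and what the validation suites do and do not establish.

## The analysis model

### Preprocessing

Each 4D image passes through mask → smooth → detrend → bandpass (the
order is configurable; smoothing before the temporal stages mirrors the
common SPM-then-REST toolchain):

- **Brain mask.** A voxel is in-brain when its temporal mean exceeds
  `mask_fraction` (default 0.2) times the 98th percentile of the
  temporal-mean image. The percentile rather than the maximum makes the
  threshold robust to isolated bright voxels. On synthetic data the
  100:1 brain/background contrast makes this mask exact.
- **Smoothing.** Per-volume 3D Gaussian convolution. The kernel is
  specified by its FWHM in mm (default 1.0) and converted per axis to a
  sigma in voxels, σ = FWHM ∕ (2√(2 ln 2)) ∕ voxel-size — 0.9055 voxels
  in-plane at 0.469 mm, 0.4247 through-plane at 1.0 mm. The kernel has
  unit sum; at grid boundaries the truncated kernel is renormalised by
  the in-grid kernel mass, so constant fields pass through unchanged.
- **Detrend.** Least-squares removal of a polynomial (default order 1,
  intercept included) from each voxel series. The residual has zero mean.
- **Bandpass.** A zero-phase "ideal" filter: the DFT is masked so that
  only coefficients with low ≤ f ≤ high (bounds inclusive; defaults
  0.002–0.1 Hz) survive, DC always removed, then inverted. This is the
  REST-toolkit style of filter; unlike an IIR design it is an exact
  projection, which gives bin-exact testable behaviour. At T = 300,
  TR = 1 s the bin spacing is 1/300 Hz, so the lowest retained frequency
  is 1/300 ≈ 0.0033 Hz (the nominal 0.002 Hz bound falls between bins).

Detrend and bandpass are individually linear, idempotent projections.
Their composition is *not* exactly idempotent in discrete time: an
integer-cycle ramp has in-band DFT energy, so the two projections do not
commute. The test suite asserts the properties that actually hold (each
stage idempotent; re-filtering the chain output is the identity) rather
than the continuous-time idealisation.

### Seed correlation and Fisher transform

The seed time course is the unweighted mean over the seed ROI's in-mask
voxels of the *preprocessed* image. Each in-mask voxel gets a Pearson
correlation with the seed; voxels with zero temporal variance are marked
invalid rather than assigned r = 0, so they can never enter a network
map. Fisher's z = atanh(r) is applied after clipping |r| at 1 − 1e−7 to
keep numerically perfect correlations finite.

### Group DMN inference

Group maps average in z-space (tanh of the mean z, per voxel, over
subjects where the voxel is valid; voxels valid in fewer than two
subjects are invalid). The DMN mask is defined by a voxelwise one-sample
t-test of the subject z values against atanh(r₀), r₀ = 0.3, one-sided
upper tail with df = n − 1, thresholded at α ∕ family. A voxel must also
have group mean r > r₀. Testing in z-space is the statistically standard
companion to the Fisher-z workflow; a flag (`space="r"`) runs the same
test on raw correlations, since workflows in this field have historically
been ambiguous about which scale the test used.

**Bonferroni family.** The family size defaults to the *group size*, not
the number of voxels: α = 0.05 over n = 9 subjects gives the per-test
level 0.005̄5 (reported as 0.0056), and n = 8 gives 0.00625 (reported as
0.0062). This convention is unconventional — correction families are
usually the number of tests — but it is the convention this workflow
historically printed, so it is the default and is surfaced in every
summary and config echo; any integer family (e.g. the voxel count, or
`"edges"` for the 300 ROI pairs) can be passed instead. Reported
thresholds are rounded to 4 decimals with ties going toward zero, which
reproduces both printed values above from their exact quotients.

**Strength comparison.** Group DMN strength is compared by pooling each
group's own DMN voxels (their group-mean z values) into two samples and
applying Welch's two-sample t-test, two-sided (a pooled-variance flag
exists). An `exclude_roi` option removes a named ROI from both masks
first. Voxels are treated as independent observations; this ignores
spatial autocorrelation and is reported as such.

### Edge-difference network

Per subject, the K×K (default 25×25) matrix of Pearson correlations
between ROI-mean preprocessed time courses. Per unordered ROI pair, the
subject correlations are Fisher-transformed and the two groups compared
with Welch's t-test, two-sided — an edge is drawn whichever group is
stronger. The Bonferroni family again defaults to the group size (the
convention matching the printed 0.0056); `family_size="edges"` applies
the conventional K(K−1)∕2 = 300 family. The one-sample and Welch
statistics are computed from their closed forms (vectorised over voxels
and edges) with `scipy.stats.t` supplying the tail probabilities; the
test suite checks them against `scipy.stats.ttest_1samp` /
`ttest_ind` as independent references.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which the pipeline is validated.

- **Geometry.** A brain-shaped ellipsoid on the acquisition grid
  (default 64×64×11, 300 volumes, TR = 1 s, 0.469×0.469×1.0 mm voxels)
  containing up to 25 disjoint ellipsoidal ROIs placed deterministically
  on a lattice, nearest-to-centre first; the seed region RSC is placed
  first, and the anatomically large caudate putamen and hippocampus get
  proportionally larger ROIs (×1.6 and ×1.4 in-plane radius). Every ROI
  has at least 8 voxels; an unplaceable ROI raises a sizing error naming
  it.
- **Latent signals.** K unit-variance series, band-limited to
  0.01–0.05 Hz — inside the analysis pass band, so the bandpass stage
  does not destroy injected structure — and mixed by the symmetric
  matrix square root of the target correlation matrix, so their
  population correlation equals the target.
- **Target matrices.** Unit diagonal, the profile's couplings
  off-diagonal, zero elsewhere. A non-PSD assembly is repaired by
  eigenvalue clipping at zero followed by unit-diagonal rescaling (the
  simplest documented repair; idempotent), and the maximum entry change
  is recorded. The bundled profiles are built from a rank-one loading
  vector, which makes them PSD by construction so no repair distorts the
  intended couplings.
- **Voxel model.** Brain voxels: baseline 100 + `snr_scale` (default 6)
  × their ROI's latent signal (unlabeled brain voxels carry none) +
  AR(1) noise (coefficient 0.3, stationary SD 4) + a linear drift with
  per-voxel slope uniform in ±`drift_amp` (default 10, peak amplitude).
  Background voxels are white noise of SD 1, giving the 100:1 contrast
  that makes intensity masking trivially exact. These levels put the
  post-filter voxel SNR high enough that an injected coupling r* appears
  in subject maps attenuated by only ≈ 10%, comfortably inside the
  ±0.15 recovery tolerance used in validation.
- **Strain profiles.** SHR-like loadings: RSC 0.90, caudate putamen
  0.82, cingulate 0.80, orbital 0.74, somatosensory 0.70, thalamus 0.60.
  WKY-like: RSC 0.80, hippocampus 0.70, cingulate 0.60, orbital 0.56,
  motor 0.50. The pairwise couplings are the loading products. The
  profiles encode the qualitative contrast under study — the SHR-like
  seed network is larger and uniformly stronger and includes the caudate
  putamen, the WKY-like network is hippocampal — with effect sizes that
  are calibration choices (no quantitative couplings exist to copy from
  in-vivo reports).
- **Determinism.** Every output is a pure function of (acquisition,
  profile, seeds). Per-subject seeds derive from
  `SeedSequence([master_seed, subject_index])`, truncated below 2³¹.

**Effective temporal sample size.** After band-limiting to 0.01–0.05 Hz
at T = 300, a latent series occupies 13 DFT bins ≈ 26 real degrees of
freedom. The null sampling SD of an ROI–ROI correlation is therefore
≈ 1∕√26 ≈ 0.20, and the validation bounds (e.g. |r| ≤ 3∕√26 for null
pairs) use T_eff = 26.

## Validation studies and their sizes

The Monte-Carlo suites run on a reduced 40×40×7 grid with the full
300-volume timecourse and the full preprocessing chain: the temporal
statistics under test are unchanged by the spatial reduction, and the
package's own choice of this size keeps the suites fast enough to run
routinely. Sizes: type-I calibration, 9 × 250 000 null voxel tests at the
exact null boundary; coupling recovery, 20 cohorts of n = 9 at each
r* ∈ {0.35, 0.5, 0.65}; strain contrast, 20 cohort pairs of n = 9 + 9.
The full 64×64×11 geometry is exercised in unit tests and by
`scripts/acceptance.py`, which runs one full-scale two-strain study.

What passing these suites shows: the statistics are computed correctly
(oracle equivalence to 1e−6), the thresholding is calibrated at its null
boundary, and injected ROI-level correlation structure propagates through
masking, smoothing, detrending, filtering and thresholding with small,
quantified attenuation. What it does not show: performance on real BOLD
data, which has hemodynamic convolution, physiological (cardiac/
respiratory) noise, motion, registration error and spatially varying
coil sensitivity, none of which are simulated.

## Known limitations

- **Own-mask strength comparison at toy scale.** The pooled two-sample
  strength test compares each group's own DMN voxels. On the synthetic
  geometry the seed ROI and its smoothing halo — voxels whose
  correlation with the seed is near 1 — form a large fraction of the
  smaller (WKY-like) mask, which raises that group's pooled mean; the
  comparison's *sign* therefore reflects mask composition rather than
  the injected network strength at this scale. The injected strength
  contrast is instead visible in the edge tests and the DMN histograms.
  The pipeline reports the pooled comparison and a seed-excluded variant
  side by side.
- No hemodynamic-response model, physiological noise, motion, or
  registration; slice-timing and alignment are out of scope.
- Voxel-pooled inference ignores spatial autocorrelation (no cluster
  or permutation correction is implemented, by design).
- The ideal bandpass assumes stationarity and wraps the series
  circularly; very low-frequency drift beyond the linear term leaks into
  the lowest retained bin.
- The toy atlas is geometric, not anatomical: ROI placement is a
  deterministic packing, not a stereotaxic atlas.
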