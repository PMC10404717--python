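# Methods

## The core network model

The package's central object is a per-subject voxelwise *target map*
built from eight seed regions in two sign classes. Each seed `k` has a
fixed MNI peak, a binarized region (by default a 6 mm sphere around the
peak; arbitrary NIfTI cluster masks may be substituted per seed), and a
sign: +1 for regulatory regions (bilateral anterior insula and dorsal
anterior cingulate cortex, positively coupled to the DLPFC) and −1 for
regulated regions (bilateral amygdala and subgenual cingulate, negatively
coupled). For a denoised BOLD series, seed connectivity is the Pearson
correlation between the seed's unweighted mean time course and every
voxel's time course over retained (uncensored) volumes; the target map is
the signed average `(1/N) Σ sign_k · r_k(v)`. Without the sign reversal
the positive and negative couplings cancel near zero — the acceptance
suite verifies this cancellation and its closed-form magnitude on
generator data. Maps are averaged in r-space; a Fisher-z-space averaging
variant exists behind a flag for methods comparison but is not the
default, since correlations of this magnitude (|r| ≲ 0.5) differ
negligibly between the two conventions and r-space is the primary
definition.

A single-seed comparison model (bilateral sgACC only) is expressed as a
`SeedSet` subset, not separate code, so any seed-set variant runs through
the identical path.

Undefined voxels (zero temporal variance, e.g. outside the head or
constant after masking) are flagged NaN and propagate through averaging
and selection; they are never silently zeroed, because a fake 0 could
displace genuine weak targets in top-K selection.

## Preprocessing

Denoising follows the standard seed-connectivity preparation, with a
fixed default order:

1. **Nuisance regression**: OLS residualization of every voxel against an
   intercept, the six rigid-body motion parameters, their element-wise
   squares (the usual quadratic expansion; a flag disables the squares),
   and mean CSF and white-matter signals. The fit uses retained volumes
   only; the fitted model is evaluated on all volumes so censored time
   points stay consistent.
2. **Bandpass** 0.01–0.1 Hz: linear detrend followed by an rFFT-domain
   mask that zeroes all bins outside the band, including DC. The contract
   is stated in power terms — passband sinusoids keep ≥ 90 % of their
   variance, stopband sinusoids (≤ half the low edge, ≥ twice the high
   edge) keep ≤ 10 % — so any realization meeting it is conforming. The
   filter is applied to the full series: with the fixed order nothing is
   censored yet at filter time, and filtering the complete array keeps
   indices aligned with the motion trace.
3. **Scrubbing**: framewise displacement in the Power convention,
   `FD(i) = Σ|Δtrans| + 50 mm · Σ|Δrot|` (rotations in radians; a trace
   whose rotation columns exceed 2π is rejected loudly as probable
   degrees). Volumes with FD > 0.5 mm are censored together with 1
   preceding and 2 following volumes. Censoring is a boolean mask —
   volumes are excluded from every later fit and correlation but never
   deleted, so scrubbing is monotone in the threshold and indices stay
   stable.

No spatial smoothing is applied anywhere; repeatability numbers therefore
reflect unsmoothed single-voxel maps.

## Target selection and group analyses

Per hemisphere (voxels with MNI x < 0 are left, x > 0 right; exact
midline voxels belong to neither, avoiding double counting), the target
is the K = 100 largest-valued defined DLPFC voxels. Ties at the K-th rank
break deterministically by value descending, then linear C-order voxel
index ascending, which makes selection monotone in K and reproducible.
The DLPFC mask is a required input; the synthetic module ships a stand-in.

Group statistics: the overlap map is `100 · (count of subjects whose
target contains v) / n`; peak distances are pairwise Euclidean distances
in mm between per-subject argmax voxels inside a hemisphere mask (single
argmax voxel, no sub-voxel interpolation); extraction at stimulated
coordinates averages the group's maps voxelwise and samples the nearest
voxel (nearest-voxel rather than interpolated sampling is a documented
choice, consistent with the voxel-level analyses elsewhere in the
package). Outcome association uses plain Pearson correlation plus a
partial correlation: both variables are residualized on an intercept and
the one-hot-encoded covariates (device, protocol, number of sessions) and
the residuals correlated, with the p-value from a t distribution at
`n − 2 − k` degrees of freedom for `k` covariate columns.

## Repeatability

A series of `n` volumes splits into `floor(n / L)` contiguous segments of
length `L`; tail volumes are dropped, matching the 1000 → 8×125 / 4×250 /
2×500 arithmetic of a standard 28-minute acquisition at TR 1.68 s.
`r_spat` for a segment length is the mean over all C(m, 2) pairwise
spatial correlations of the segment maps within the bilateral DLPFC mask.
Scan time for a segment is `L · TR / 60` minutes from nominal volume
counts; a censoring-adjusted effective-time mode would change only the
abscissa and is intentionally not the default.

The scan-time model `r_spat(t) = r_spatmax − exp(−t/a)` is fitted by
bounded nonlinear least squares (`r_spatmax ∈ (0, 1]`, `a > 0`),
initialized at `r_spatmax₀ = max(r) + 0.05` (clipped to 1) and
`a₀ = median(t)` so fits are reproducible; non-convergence is returned as
an explicit status. With two points the model interpolates exactly. Both
pooled (all subject points) and group-mean fitting are possible since the
fit accepts any (t, r) collection.

Fisher's z transform (`atanh`) is applied to correlations before paired
t-tests; the test rejects zero-dispersion differences where t is
undefined. Explained-variance fold changes between two repeatability
values are `(r_a / r_b)²`.

## The synthetic generator

The generator produces the minimal statistical structure that makes
sign-reversed averaging provably beneficial: one shared band-limited
(0.01–0.1 Hz) zero-mean unit-variance Gaussian latent `u(t)` and voxel
series `x_v(t) = w_v · u(t) + ε_v(t)` with iid N(0, 1) noise. Weights are
+snr in regulatory seeds, −snr in regulated seeds, 0 in background, and
Gaussian-tapered `snr · exp(−d²/(2σ²))` (σ = radius/2) inside the planted
bilateral DLPFC target clusters, so connectivity — and the simulated
treatment outcome — varies smoothly in space. Under this model the
expected voxel-to-seed correlation has the closed form
`w·snr / sqrt((w² + 1)(snr² + 1/m))` for an m-voxel seed, and every test
expectation derives from it; ground-truth files (cluster voxels, weights,
seed sizes, outcome parameters) suffice to recompute all expected values
without rerunning the generator.

Default conditions, chosen once as a realistic desk-scale emulation of
the acquisition the pipeline addresses: 1000 volumes at TR 1.68 s (125
volumes = 3.5 min), 6 mm seed spheres, 7.5 mm target clusters centred at
(±38, 44, 26) mm, per-subject jitter SD 3 mm, snr 0.3 (expected
peak-voxel map values ≈ 0.25, the magnitude typical of seed-based
connectivity), motion wobble SD 0.02 mm with optional 1 mm displacement
spikes, and outcomes linear in ground-truth connectivity at a stimulated
coordinate scattered 2 mm around the subject's left target centre, plus
device/protocol/session covariate effects and Gaussian noise.

The grid is 31×28×26 voxels of 3 mm with origin (−45, −24, −30) mm — the
smallest box containing all eight seed peaks and the bilateral DLPFC
region — so full-pipeline tests run in seconds. Cohorts are
bit-reproducible: subject `i` draws from `SeedSequence([cohort_seed, i])`
(outcome randomness from `[cohort_seed, i, 1]`), so adding subjects never
perturbs existing ones.

What the generator does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, spatial autocorrelation of
noise, scanner drift, susceptibility dropout near sgACC, or inter-subject
anatomical variability beyond target jitter. Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the model under its own assumptions — not that real-data repeatability or
effect sizes will match.

## Problem sizes and numerical choices

Tests and the acceptance script scale simulations to desk size as the
package's own study design: localization uses 100 replicates of
120-volume high-SNR (snr 5) subjects; the repeatability curve uses 4
subjects at the full 1000 volumes; null calibration uses 12 signal-free
250-volume subjects plus 10,000 vectorized paired-test nulls;
jitter-distance comparisons use 6-subject cohorts at 150 volumes. All
stochastic checks run from fixed or caller-provided seeds.

Numerical details worth knowing: correlations are clipped to [−1, 1]
against floating-point overshoot; the voxel matrix is centred once per
map computation and all eight seed correlations reuse it; zero-variance
denominators produce NaN flags rather than warnings; rank-deficient
nuisance designs raise an error naming the first collinear column; the
exponential fit uses tight tolerances (1e-14) so noiseless model points
are recovered to ≤ 1e-6.

## Known limitations

* Seed regions are spheres around published peaks, not the original
  database-derived cluster shapes; user-supplied cluster masks are the
  escape hatch.
* The DLPFC mask must be provided (or taken from the synthetic stand-in);
  the package does not construct it.
* The repeatability inference treats DLPFC voxels as independent
  observations when correlating maps; no spatial-autocorrelation
  correction is applied.
* Real-data group results (e.g. absolute r_spat levels or
  clinical-outcome correlations) depend on scanner, task and population
  and are outside what the synthetic suite can certify.
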