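# Methods

## The inference problem

Single-subject fMRI activation mapping tests, for each of ~20 000 brain
voxels, whether a time series of 80–150 BOLD samples contains a
task-locked response. Parametric thresholds (Student-t, Bonferroni, random
field theory) require Gaussian, temporally independent noise and a
statistic whose null distribution is known in closed form — assumptions
that fail for real fMRI noise and for adaptive statistics such as
restricted CCA, whose null distribution has no known form at all.

`permfmri` implements the nonparametric alternative: a random (Monte
Carlo) permutation test on surrogate null data, with the multiple-testing
problem solved by the distribution of the **maximum** statistic over the
brain. Only the maximum value of each surrogate map is kept; the sorted
maxima directly give a family-wise-error (FWE) corrected threshold and
corrected per-voxel p-values

    p_c(v) = #{ i : max_i >= t(v) } / N_p .

With `N_p` permutations the relative standard deviation of an estimated
p-value is `sqrt(p(1-p)/N_p)/p` — 4.36 % for p = 0.05 at N_p = 10 000 —
which is what `permfmri perm-accuracy` tabulates.

## The surrogate-data pipeline

Permuting raw fMRI series is invalid: temporal autocorrelation breaks
exchangeability. The pipeline therefore runs, per voxel series:

1. **Cubic detrending** — projection onto the orthogonal complement of an
   orthonormalized polynomial basis of degree 0–3 (built on normalized
   time in [-1, 1] for conditioning).
2. **BOLD removal** — OLS removal of the design matrix, leaving residual
   (null) data.
3. **AR(p) estimation** (Yule–Walker on biased autocovariances; default
   p = 4, configurable 1–8), with two refinements described below:
   projection-bias correction and spatial pooling.
4. **Whitening** `e_t = y_t - sum_k a_k y_{t-k}` (zero initial state),
   iterated three times with re-estimation; the three filters compose to
   the accumulated whitening operator.
5. **Per permutation**: one random time permutation applied to *all*
   voxels (spatial structure is preserved; the permutation matrix is
   `N_p x N_t`, seeded), inverse whitening by simulating the AR model
   with the permuted innovations, **smoothing**, detrending, the
   statistic, and the maximum over the mask.

Smoothing is applied *inside* every permutation. Smoothing before
whitening would change the AR estimates with the filter width; smoothing
the innovations would distort the simulated noise. A surrogate null
dataset must have the same properties regardless of the analysis applied
to it, so the data are first generated, then analysed.

### Projection-bias correction of the AR estimates

Steps 1–2 remove six of the 80 temporal degrees of freedom. The residual's
sample autocovariances are then systematically distorted:
`E[c_hat_k] = sum_l M_kl gamma_l`, with `M` computable from the projection
matrix. An AR model fitted to the raw `c_hat` absorbs the artifact; the
permutation then destroys the artifact but the inverse whitening re-imposes
it, so the surrogate maxima are biased — measurably so (empirical FWE near
0.5 instead of 0.05 at reduced scale, even for white noise). The estimator
therefore solves `M gamma = c_hat` before the Yule–Walker step, with the
projected-out basis carried through the whitening iterations (using the
spatial-mean filter as a shared approximation). The lag window of the
solve is 12 (at least p+1): wide enough to capture the covariance mass the
projection redistributes, short enough not to amplify sampling noise —
estimator noise in the AR field inflates the surrogate maxima through the
convexity of recoloring and the max statistic.

### Spatial pooling (variance pooling)

Eighty samples are too few for stable per-voxel AR(4) estimates. The
coefficient volumes are smoothed with a Gaussian of 8 mm FWHM using
**normalized convolution**, `cwr = ((c . s) * f) / (c * f)`, with
certainty `c` = 1 inside the brain mask and 0 outside, so near-zero
AR values from outside the brain never bias edge voxels. Pooling is
configurable, including off. Pooled coefficient vectors whose
characteristic roots reach modulus 0.99 are shrunk radially to 0.98 so no
surrogate can diverge.

### Whiteness diagnostics

The Ljung–Box statistic
`Q = N_t (N_t + 2) sum_{k<=h} r(k)^2 / (N_t - k)` is compared against the
chi-square quantile with `h - p` degrees of freedom (so only lag counts
`h > p` are testable). Because the whitening uses pooled coefficients, the
per-lag autocorrelation volumes are pooled the same way before computing
Q. `whiteness_map` reports flagged-voxel counts over lag counts 1–10 (the
mean across tested `h`), and the engine can optionally drop voxels that
remain nonwhite from the permutation test (`exclude_nonwhite`).

A caution the diagnostics cannot remove: in-sample residuals of an
in-sample-fitted AR model look white by construction. Passing the
Ljung–Box test shows the model matched the *residual's* spectrum, not that
the surrogate spectrum matches the truth — which is why the projection
correction above matters even though uncorrected residuals pass the test.

## Detection statistics

**GLM.** `beta = (X'X)^{-1} X'Y`, `t = c'beta / sqrt(var(e) c'(X'X)^{-1}c)`
with the unbiased residual variance (denominator `nt - k`). The design has
two columns — the block paradigm convolved with a canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot
ratio 1/6, 32 s support; convolution on a 0.1 s grid, derivative by
central differences) and its temporal derivative — mean corrected, unit
normalized, orthogonalized. The contrast defaults to (1, 0). A global
AR(1) prewhitening of data and design is available; by default it is off,
because the permutation test only needs the observed and surrogate
statistics to be the *same* quantity (a pseudo-t is fine), and it is
switched on (for the original map and every permutation alike) only when
comparing against parametric thresholds.

**CCA.** The canonical correlation
`rho = max corr(X beta, F gamma)` pairs the temporal basis with per-voxel
responses `F` under a bank of spatial filters, so the analysis chooses the
smoothing adaptively. Second moments are taken about zero (pipeline data
are detrended). The **restricted** variant constrains `gamma >= 0`
elementwise (any synthesized filter is a nonnegative lowpass) and
`beta_1 >= 0` (non-inverted HRF), solved exactly by enumerating
active-constraint faces — each face is an unconstrained CCA on a reduced
basis, and the feasible maximum over at most `2 (2^m - 1)` small
eigenproblems is the global optimum. Covariances receive a relative ridge
of 1e-10 before inversion.

Filter banks:

- **2D (four filters, slicewise):** one small isotropic Gaussian plus
  three elliptical Gaussians (2:1 axis ratio) at 0°, 60° and 120°. The
  long-axis width is calibrated numerically so that the *largest* filter
  CCA can form — the equal-weight sum — best-fits an isotropic Gaussian of
  FWHM `fwhm_max` (relative L2 residual ~4.5 %); the small filter is 0.6x
  the long axis. Kernels are evaluated with 5x subpixel cell-averaging
  (short-axis sigmas are sub-voxel at 8 mm / 3.75 mm) on 5-sigma square
  supports (tighter supports truncate orientation-dependent corner mass
  and break the 60° symmetry).
- **3D (two filters):** an isotropic Gaussian at `sigma_0 = fwhm_max /
  (2 sqrt(8 ln 2))` and its analytic derivative with respect to sigma;
  `g + w dg/dsigma` approximates Gaussians of width `sigma_0 + w`, giving
  scale-adaptive but isotropic smoothing.

With a single spatial filter CCA reduces algebraically to regression
(`rho^2 = R^2`) — for the *unrestricted* statistic; the restriction can
bind at voxels with anticorrelated response, which is why `cca_map` exposes
`restricted=False` for such comparisons. The analytic null of the sample
canonical correlations (independent Gaussians, `N` samples, dimensions
`n`, `m`) is evaluated as the classical ordered joint density of the
*squared* coefficients and normalized numerically (midpoint rule; m <= 2);
for m = 1, n = 2 it reduces to `rho^2 ~ Beta(1, (N-2)/2)`, which the test
suite verifies against Monte Carlo.

## Thresholds and conventions

- Corrected threshold: ascending-sorted maxima, 1-based position
  `ceil((1 - alpha) N_p)` — position 9500 for N_p = 10 000, alpha = 0.05.
  Fewer than `1/alpha` permutations trigger a resolution warning.
- Maxima are one-sided (signed maximum) by default, matching an
  activation-mapping focus; `two_sided=True` records `max |t|`.
- Bonferroni comparison: upper `alpha/N_v` Student-t quantile at
  `df = nt - k`.
- RFT comparison: solves expected-Euler-characteristic = alpha for a
  t-field, with resel counts from lattice counting (voxels, in-mask
  neighbour pairs, faces, cubes) and the standard EC densities; provided
  for comparison only and warns when the smoothness is below one voxel.
- The identity permutation is not excluded from the plan (probability
  1/N_t!).
- Permutations are independent given the plan; any execution order or
  batching yields identical sorted maxima (tested).

## Synthetic data

`generate_synthetic` emulates the target acquisition: defaults 64x64x22
voxels, 80 volumes, TR 2 s, 3.75 mm isotropic voxels, a central ellipsoid
"brain" (~25 % of the volume, ~20 000 voxels at full size), 20 s on /
20 s off blocks. Per in-brain voxel: polynomial trend (degree <= 3 in
normalized time; default baseline 100 with drift coefficients (1, 0.5,
0.25), a few percent of baseline over the run), optional HRF-convolved
block activation scaled as `amplitude x noise_sd` at the response peak,
and AR(p)-filtered Gaussian innovations with standard deviation
`noise_sd` (white by default; constant or spatially varying coefficient
fields supported, stationarity enforced, 100-sample burn-in). Outside the
brain only faint background noise remains, so intensity thresholding
(`make_mask`, default 0.2 of the maximum mean intensity) recovers the
brain. A Rician magnitude-noise option exists (off by default — the
pipeline itself never assumes Rician noise).

What the generator does *not* emulate: motion, slice-timing offsets,
physiological (cardiac/respiratory) noise, scanner spikes, spatial noise
correlations, and non-AR long-memory structure. Passing tests therefore
show the statistical machinery is correct under its own model, not that
real acquisitions satisfy that model.

## Problem sizes used by the tests and the acceptance script

The validation experiments run at reduced scale, chosen as the smallest
grids that leave the checked statistics well resolved: FWE calibration on
a 20x20x10 grid with 80 volumes (40 000 permutations in the test suite;
100 000, the full validation count, in `scripts/acceptance.py`; 10 000
fresh datasets in both), whiteness validation on 14x14x6, recovery on
16x16x4 with 1 000 permutations, threshold variability on 6x6x2 with
400 vs 4 000 permutations.

## Known limitations

- Under strongly autocorrelated noise (AR weight sums ~0.5 at 80
  samples), surrogate calibration retains a small liberal bias (measured
  empirical FWE ~0.08 at nominal 0.05 at reduced scale): the bias/variance
  compromise of the debiased AR estimator cannot be escaped at this series
  length. White or mildly correlated noise calibrates within binomial
  error.
- The first `p` samples of whitened series are only partially whitened
  (zero initial conditions); the accumulated AR field reported for
  inspection is truncated to order `p` (with a warning when the dropped
  polynomial mass exceeds 1e-6), while inverse whitening always uses the
  exact per-iteration filter sequence.
- The 2D bank is slicewise by construction; through-plane adaptivity
  requires the 3D pair, which is scale- but not orientation-adaptive.
- Step-down/step-up procedures, cluster-extent and cluster-mass
  statistics, and multi-subject inference are out of scope.
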