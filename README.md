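# permfmri

Fast random permutation tests for single-subject fMRI activation mapping,
with family-wise error control via the maximum statistic.

Parametric thresholds for fMRI activity maps (Student-t with Bonferroni or
random-field-theory correction) assume Gaussian, temporally independent
noise and a detection statistic with a known null distribution. Real fMRI
noise is neither Gaussian nor independent, and for adaptive statistics such
as restricted canonical correlation analysis (CCA) no null distribution is
known at all. `permfmri` is for researchers who want corrected inference
that does not lean on those assumptions: it estimates the null
distribution of the **maximum** test statistic over the brain by analysing
thousands of surrogate null datasets, which makes activity maps from
*different* statistics — the standard GLM and adaptive restricted CCA —
comparable at the same significance level.

## The method

For each voxel time series `Y` (nt samples, TR-spaced) and design `X`
(block paradigm convolved with a double-gamma HRF and its temporal
derivative; mean corrected, normalized, orthogonalized):

- **GLM:** `beta = (X'X)^-1 X'Y`, `t = c'beta / sqrt(var(e) c'(X'X)^-1 c)`.
- **Restricted CCA:** `rho = max corr(X beta, F gamma)` over temporal
  weights `beta` and nonnegative spatial-filter weights `gamma`, where `F`
  holds the voxel's responses under a bank of smoothing filters (2D: one
  small isotropic + three oriented anisotropic Gaussians; 3D: a Gaussian
  and its scale derivative) — adaptive smoothing chosen per voxel.

Surrogate null data are built per voxel by cubic detrending, removal of
the fitted BOLD component, AR(4) whitening (Yule-Walker estimates,
projection-debiased, spatially pooled by 8 mm normalized convolution,
iterated three times), a random time permutation shared by all voxels, and
inverse whitening. Smoothing and the statistic run **inside each
permutation**, and only the maximum over the brain is kept. Sorting the
`N_p` maxima gives the corrected threshold (position `ceil((1-alpha) N_p)`)
and exact corrected p-values

```
p_c(voxel) = #{ i : max_i >= t_voxel } / N_p .
```

Bonferroni and random-field-theory thresholds are computed alongside for
comparison. See `docs/methods.md` for the full model description,
numerical choices and limitations.

## Worked example

Simulate a block-design acquisition (24x24x8 voxels, 80 volumes, TR 2 s,
20 s on / 20 s off, an 8-voxel active blob at 3x the noise sd) and analyse
it with both statistics at 1000 permutations:

```
$ permfmri simulate --spec myspec.json --out scratch/sim   # or the API
$ permfmri analyze --data scratch/bold.nii.gz --mask scratch/mask.nii.gz \
    --paradigm scratch/paradigm.tsv --stat glm --fwhm 8 \
    --permutations 1000 --seed 1 --out scratch/out_glm
glm: corrected P=0.05 threshold 4.0661, 42 significant voxels of 1416
```

The threshold 4.07 is the 950th of 1000 sorted surrogate maxima: the
t-value a brain-wide maximum exceeds by chance only 5% of the time, so the
42 suprathreshold voxels (the true blob plus its smoothing halo) are
significant with family-wise error 0.05. The summary JSON also reports the
parametric comparisons — Bonferroni 4.20 and RFT 4.43 for this mask —
and the output directory contains the statistic map, the corrected p-map
and `1 - p` map (NIfTI), and the sorted maxima (CSV). Running the same
command with `--stat cca2d` thresholds the restricted canonical
correlation map at the same corrected level (threshold 0.4832, 36
significant voxels), which is how the two detection methods are compared
fairly.

How many permutations are enough? The accuracy calculator prints the
relative standard deviation of the estimated p-value:

```
$ permfmri perm-accuracy --pvalue 0.05 --permutations 10000
P = 0.05 with 10000 permutations: relative sd 4.36%
```

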