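# pcadenoise

PCA denoising of redundant MRI data — diffusion-weighted series in
particular — with three eigenvalue-classification criteria and the
supporting machinery to validate them on a synthetic phantom with
spatially correlated noise.

## The problem

A sliding window over a 4D volume collects the `N` redundant measurements of
its `M` voxels into a Casorati matrix `X` (`M ≥ N`). After removing each
column's mean, the eigenvalues `λ₁ ≤ … ≤ λ_N` of the covariance
`XᵀX / M` split into a low-rank signal part and a noise bulk that, for iid
noise of variance `σ²`, follows the Marčenko–Pastur (MP) law supported on

```
λ± = σ² (1 ± √γ)²,   γ = N/M .
```

Zeroing the `C` noise components and projecting back denoises the window
(nominal SNR gain `N/(N−C)`); overlapping windows are combined by
overcomplete averaging. Everything hinges on choosing `C`:

- **MPPCA** (moment matching): remove the largest eigenvalues until the mean
  `λ̄_c` of the retained set reaches the variance implied by its MP
  bandwidth, `σ̂²_MP = (max λ_c − min λ_c) / (4√(C/M))`. Needs no prior, but
  assumes the MP shape — which spatially *correlated* noise (partial-Fourier
  zero-filling, smoothing, interpolation) breaks: the criterion then keeps
  nearly everything and no denoising happens.
- **GPCA** (general PCA): largest `C` with `λ̄_c ≤ σ̂²_prior`, where
  `σ̂²_prior` is estimated independently (sample variance across repeated
  b=0 images, median per window). The eigenvalue mean is an unbiased
  variance estimator even under correlated noise, so GPCA keeps working.
- **TPCA** (threshold PCA): classify eigenvalues below
  `λ_t = (1 + √γ)² σ̂²_prior` as noise — only the MP upper bound is used.
  Slightly conservative (a couple of correlated-noise eigenvalues can escape
  the bound) but markedly more robust to an over-estimated prior than GPCA.

The package implements the three classifiers (plus the legacy
`τ = υ²σ²` threshold and an MP spectrum-fitting variant), the
noise-prior estimation from b=0 repeats, the sliding-window denoising
engine with NIfTI I/O, a synthetic two-compartment diffusion phantom whose
ground-truth component count is exactly 8, and k-space zero-filling /
Gaussian smoothing to manufacture spatially correlated noise.

## Worked example

`examples/01_denoise_phantom.py` builds the 12×12 phantom (9 homogeneous
4×4 portions, 110-measurement protocol), adds Gaussian noise at SNR 30 and
classifies the single 144×110 window:

```
window matrix: 144 voxels x 110 measurements
mppca  kept   8 signal / 102 noise components, SNR gain 13.75, RMSE 0.0334 -> 0.0120
gpca   kept   8 signal / 102 noise components, SNR gain 13.75, RMSE 0.0334 -> 0.0120
tpca   kept   8 signal / 102 noise components, SNR gain 13.75, RMSE 0.0334 -> 0.0120
```

All three criteria recover the ground-truth 102/8 split and cut the signal
RMSE ~2.8×. `examples/03_correlated_noise_failure.py` repeats this after
zero-filling 3 of 12 k-space columns:

```
mppca  -> 109 signal components (ground truth 8)
gpca   ->   8 signal components (ground truth 8)
tpca   ->   9 signal components (ground truth 8)
```

MPPCA collapses (no denoising); GPCA recovers the split exactly; TPCA lets
the occasional widened-spectrum eigenvalue escape the bound.
`examples/04_prior_robustness.py` shows why TPCA is still worth having: at a
4× over-estimated prior GPCA is down to 5 signal components (it removes true
signal) while TPCA still reports 8.

## Command line

A thin CLI wraps the same functions:

```sh
pcadenoise phantom --size 12 --snr 30 --correlate zerofill:3 --seed 42 --out-prefix exp2
pcadenoise noisemap exp2_processed_noisy.nii.gz exp2.bval --out sigma2.nii.gz
pcadenoise denoise exp2_processed_noisy.nii.gz exp2.bval exp2.bvec \
    --method tpca --window 11x11 --noise-map sigma2.nii.gz --out denoised.nii.gz
pcadenoise evaluate --denoised denoised.nii.gz --raw exp2_processed_noisy.nii.gz \
    --truth exp2_processed_clean.nii.gz --report report.json
```

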