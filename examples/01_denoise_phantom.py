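"""Denoise the synthetic phantom and count preserved signal components.

Builds the 12 x 12 two-compartment diffusion phantom (110 measurements),
corrupts it with iid Gaussian noise at SNR 30, and runs the three eigenvalue
classifiers on the single 144 x 110 window. The phantom is built from 9
homogeneous portions, so after column demeaning exactly 8 principal
components carry signal; a correct classifier labels the other 102 as noise.
"""

import numpy as np

import pcadenoise as pcd

snr = 30.0
ds = pcd.add_noise(pcd.build_phantom(), sigma=1 / snr, seed=42)
sigma2 = (1 / snr) ** 2  # exact noise variance prior for GPCA/TPCA

X = ds.matrix("noisy")  # 144 voxels x 110 measurements
truth = ds.matrix("clean")

print(f"window matrix: {X.shape[0]} voxels x {X.shape[1]} measurements")
for method in ("mppca", "gpca", "tpca"):
    prior = None if method == "mppca" else sigma2
    denoised, cls = pcd.denoise_matrix(X, method, sigma2_prior=prior)
    rmse_raw = np.sqrt(np.mean((X - truth) ** 2))
    rmse_den = np.sqrt(np.mean((denoised - truth) ** 2))
    print(f"{method:6s} kept {cls.n_signal:3d} signal / {cls.n_noise:3d} noise "
          f"components, SNR gain {cls.snr_gain:5.2f}, "
          f"RMSE {rmse_raw:.4f} -> {rmse_den:.4f}")

# All three methods should report 8 signal components: the noise floor drops
# by sqrt(SNR gain) ~ 3.7x while the rank-8 signal subspace is untouched.
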