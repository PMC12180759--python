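import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcadenoise as pcd
from conftest import spectrum_from


class TestDemean:
    def test_constant_matrix(self):
        X = np.full((4, 3), 7.0)
        Xc, means = pcd.demean_columns(X)
        assert np.all(Xc == 0)
        assert np.all(means == 7.0)

    def test_single_column(self):
        Xc, means = pcd.demean_columns(np.array([[1.0], [3.0]]))
        assert Xc.tolist() == [[-1.0], [1.0]]
        assert means[0] == 2.0

    def test_random_columns_sum_to_zero(self, rng):
        Xc, _ = pcd.demean_columns(rng.normal(size=(5, 3)))
        assert np.allclose(Xc.sum(axis=0), 0.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pcd.demean_columns(np.ones((1, 3)))


class TestEigendecompose:
    def test_zero_matrix(self):
        spec = pcd.eigendecompose(np.zeros((6, 3)))
        assert np.all(spec.eigenvalues == 0)

    def test_rank_one_trace_identity(self, rng):
        u = rng.normal(size=(8, 1))
        v = rng.normal(size=(1, 4))
        Xc = u @ v
        spec = pcd.eigendecompose(Xc)
        nonzero = spec.eigenvalues > 1e-12 * spec.eigenvalues.max()
        assert nonzero.sum() == 1
        assert spec.eigenvalues[-1] == pytest.approx(np.sum(Xc**2) / 8)

    def test_orthonormal_eigenvectors(self, rng):
        spec = pcd.eigendecompose(rng.normal(size=(20, 6)))
        assert np.allclose(spec.eigenvectors.T @ spec.eigenvectors, np.eye(6),
                           atol=1e-10)

    def test_rejects_wide_and_nonfinite(self, rng):
        with pytest.raises(ValueError):
            pcd.eigendecompose(rng.normal(size=(3, 5)))
        bad = np.ones((5, 3)); bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            pcd.eigendecompose(bad)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_energy_conservation(self, seed):
        """Eigenvalue sum times M equals the demeaned Frobenius energy."""
        r = np.random.default_rng(seed)
        Xc, _ = pcd.demean_columns(r.normal(size=(12, 5)))
        spec = pcd.eigendecompose(Xc)
        assert spec.eigenvalues.sum() * 12 == pytest.approx(np.sum(Xc**2), rel=1e-10)

    def test_noise_free_phantom_has_rank_eight(self, clean_phantom):
        """The 9-portion construction yields exactly 8 signal components."""
        Xc, _ = pcd.demean_columns(clean_phantom.matrix("clean"))
        spec = pcd.eigendecompose(Xc)
        lam = spec.eigenvalues
        assert int((lam > 1e-8 * lam.max()).sum()) == 8


class TestClassifiers:
    def test_mppca_hand_example(self):
        # At C=4: mean 25.75 < (100-1)/(4*sqrt(4/16)) = 49.5 fails;
        # at C=3: mean 1 >= 0 holds.
        cls = pcd.classify_mppca(spectrum_from([1, 1, 1, 100], M=16))
        assert cls.n_noise == 3
        assert cls.lambda_bar_c == pytest.approx(1.0)

    def test_mppca_flat_spectrum_keeps_all(self):
        cls = pcd.classify_mppca(spectrum_from([2.0] * 6, M=24))
        assert cls.n_noise == 6

    def test_gpca_hand_example(self):
        spec = spectrum_from([0.5, 1.0, 1.5, 10.0], M=16)
        assert pcd.classify_gpca(spec, 1.05).n_noise == 3
        assert pcd.classify_gpca(spec, 0.0).n_noise == 0
        assert pcd.classify_gpca(spec, 100.0).n_noise == 4
        with pytest.raises(ValueError):
            pcd.classify_gpca(spec, -1.0)

    def test_tpca_hand_example(self):
        spec = spectrum_from([0.5, 1.0, 1.5, 10.0], M=16)
        cls = pcd.classify_tpca(spec, 1.05)
        assert cls.threshold == pytest.approx(2.3625)
        assert cls.n_noise == 3
        assert pcd.classify_tpca(spec, 0.0).n_noise == 0

    def test_legacy_hand_example(self):
        spec = spectrum_from([0.5, 1.0, 1.5, 10.0], M=16)
        assert pcd.classify_legacy(spec, 1.0, 1.5).n_noise == 3
        assert pcd.classify_legacy(spec, 100.0, 1.0).n_noise == 4
        with pytest.raises(ValueError):
            pcd.classify_legacy(spec, 1.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 5.0, 10.0]),
                    min_size=1, max_size=12),
           st.sampled_from([0.0, 0.3, 0.6, 1.0, 1.6, 3.0, 11.0]))
    def test_gpca_tpca_match_brute_force(self, lam, prior):
        """Classifier outputs equal exhaustive search on small gridded spectra."""
        lam = sorted(lam)
        spec = spectrum_from(lam, M=4 * len(lam))
        brute_g = max((c for c in range(len(lam) + 1)
                       if c == 0 or np.mean(lam[:c]) <= prior))
        assert pcd.classify_gpca(spec, prior).n_noise == brute_g
        lam_t = (1 + np.sqrt(spec.gamma)) ** 2 * prior
        assert pcd.classify_tpca(spec, prior).n_noise == sum(x < lam_t for x in lam)

    def test_monotone_in_prior(self, rng):
        lam = np.sort(rng.gamma(2.0, 1.0, size=30))
        spec = spectrum_from(lam, M=90)
        priors = np.linspace(0.0, lam.max() * 1.5, 50)
        for fn in (pcd.classify_gpca, pcd.classify_tpca):
            counts = [fn(spec, p).n_noise for p in priors]
            assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(40, 12))
        a = 3.7
        spec1 = pcd.eigendecompose(pcd.demean_columns(X)[0])
        spec2 = pcd.eigendecompose(pcd.demean_columns(a * X)[0])
        assert np.allclose(spec2.eigenvalues, a**2 * spec1.eigenvalues, rtol=1e-9)
        assert pcd.classify_mppca(spec1).n_noise == pcd.classify_mppca(spec2).n_noise
        for fn in (pcd.classify_gpca, pcd.classify_tpca):
            assert fn(spec1, 0.8).n_noise == fn(spec2, a**2 * 0.8).n_noise


class TestMppcaSlow:
    def test_recovers_pure_noise_spectrum(self, rng):
        X = rng.standard_normal((2000, 500))
        spec = pcd.eigendecompose(pcd.demean_columns(X)[0])
        cls = pcd.classify_mppca_slow(spec)
        assert cls.n_noise == 500
        assert cls.sigma2_mp == pytest.approx(1.0, abs=0.05)

    def test_single_spike_excluded(self, rng):
        X = rng.standard_normal((2000, 500))
        v = rng.standard_normal(500)
        v /= np.linalg.norm(v)
        X = X + 3.0 * np.outer(rng.standard_normal(2000), v)
        spec = pcd.eigendecompose(pcd.demean_columns(X)[0])
        assert pcd.classify_mppca_slow(spec).n_noise == 499

    def test_correlated_noise_failure_mode(self, rng):
        """Zero-filled noise defeats MP-spectrum fitting (few/no noise comps)."""
        pn = pcd.zerofill_correlate(rng.standard_normal((12, 12, 110)), 3)
        spec = pcd.eigendecompose(pcd.demean_columns(pn.reshape(144, 110))[0])
        assert pcd.classify_mppca_slow(spec).n_noise < 20


class TestReconstruct:
    def test_zero_components_is_identity(self, rng):
        X = rng.normal(size=(10, 4))
        Xc, means = pcd.demean_columns(X)
        spec = pcd.eigendecompose(Xc)
        assert np.allclose(pcd.reconstruct(Xc, spec, 0, means), X, atol=1e-12)

    def test_all_components_leaves_means(self, rng):
        X = rng.normal(size=(10, 4))
        Xc, means = pcd.demean_columns(X)
        spec = pcd.eigendecompose(Xc)
        out = pcd.reconstruct(Xc, spec, 4, means)
        assert np.allclose(out, np.tile(means, (10, 1)))

    def test_projection_onto_true_subspace_is_lossless(self, clean_phantom):
        """Removing the 102 noise dims of the rank-8 matrix changes nothing."""
        X = clean_phantom.matrix("clean")
        Xc, means = pcd.demean_columns(X)
        spec = pcd.eigendecompose(Xc)
        out = pcd.reconstruct(Xc, spec, 102, means)
        assert np.allclose(out, X, rtol=0, atol=1e-8 * np.abs(X).max())


class TestSnrGain:
    def test_values(self):
        assert pcd.snr_gain(110, 0) == 1.0
        assert pcd.snr_gain(110, 102) == pytest.approx(13.75)
        assert pcd.snr_gain(110, 100) == pytest.approx(11.0)

    def test_full_removal_undefined(self):
        with pytest.raises(ValueError):
            pcd.snr_gain(10, 10)


def test_eigenvalue_mean_unbiased_under_correlated_noise(rng):
    """The all-eigenvalue mean tracks the post-processing voxel variance even
    for spatially correlated (zero-filled) pure noise."""
    means, varis = [], []
    for _ in range(200):
        pn = pcd.zerofill_correlate(rng.standard_normal((12, 12, 60)), 3)
        Xc, _ = pcd.demean_columns(pn.reshape(144, 60))
        spec = pcd.eigendecompose(Xc)
        means.append(spec.eigenvalues.mean())
        varis.append(pn.var())
    assert np.mean(means) == pytest.approx(np.mean(varis), rel=0.02)


class TestDenoiseVolume:
    def test_single_window_phantom_all_methods(self, clean_phantom):
        """One 144x110 window at SNR 30: every criterion keeps 8 components."""
        ds = pcd.add_noise(clean_phantom, 1 / 30, seed=3)
        s2 = (1 / 30) ** 2
        nmap = np.full((12, 12, 1), s2)
        data = ds.noisy[:, :, None, :]
        for method in ("mppca", "gpca", "tpca"):
            res = pcd.denoise_volume(data, (11, 11), method=method, noise_map=nmap)
            # windows are 11x11 on a 12x12 grid -> 4 windows; pad to full grid
            kept = res.ncomp_map[res.ncomp_map >= 0]
            assert kept.size == 4
        full = pcd.denoise_volume(data, (11, 11), method="gpca", noise_map=nmap)
        assert full.denoised.shape == data.shape
        assert np.array_equal(full.residuals, full.denoised - data)

    def test_full_grid_window_keeps_eight(self, clean_phantom):
        ds = pcd.add_noise(clean_phantom, 1 / 30, seed=3)
        s2 = (1 / 30) ** 2
        # grid is 12x12 and windows must be odd; denoise the matrix directly
        for method, prior in (("mppca", None), ("gpca", s2), ("tpca", s2)):
            _, cls = pcd.denoise_matrix(ds.matrix("noisy"), method, sigma2_prior=prior)
            assert cls.n_signal == 8

    def test_pure_noise_tpca_variance_accounting(self, rng):
        """Removing C of N noise components removes about C/N of the variance."""
        sigma = 0.1
        vol = sigma * rng.standard_normal((8, 8, 1, 40))
        res = pcd.denoise_volume(vol, (5, 5), method="tpca",
                                 noise_map=np.full((8, 8, 1), sigma**2))
        kept = res.ncomp_map[res.ncomp_map >= 0]
        C = 40 - kept.mean()
        removed = vol - res.denoised
        assert np.var(removed) / sigma**2 == pytest.approx(C / 40, rel=0.15)

    def test_transposed_window_runs(self, rng):
        """Windows with fewer voxels than measurements use the transposed math."""
        vol = rng.standard_normal((4, 4, 1, 20))  # M=9 < N=20 for 3x3 window
        res = pcd.denoise_volume(vol, (3, 3), method="mppca")
        assert res.denoised.shape == vol.shape
        kept = res.ncomp_map[res.ncomp_map >= 0]
        assert np.all(kept <= 9)

    def test_deterministic(self, rng):
        vol = rng.standard_normal((6, 6, 1, 10))
        r1 = pcd.denoise_volume(vol, (5, 5), method="mppca")
        r2 = pcd.denoise_volume(vol, (5, 5), method="mppca")
        assert np.array_equal(r1.denoised, r2.denoised)

    def test_requires_noise_map(self, rng):
        with pytest.raises(ValueError):
            pcd.denoise_volume(rng.normal(size=(6, 6, 1, 4)), (3, 3), method="gpca")

    def test_window_too_large(self, rng):
        with pytest.raises(ValueError):
            pcd.denoise_volume(rng.normal(size=(4, 4, 1, 4)), (5, 5), method="mppca")
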