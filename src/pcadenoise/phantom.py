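"""Synthetic two-compartment diffusion phantom with controllable noise.

The phantom is a square voxel grid split into a 3 x 3 arrangement of equally
sized portions. Every voxel of a portion carries the same noise-free signal
from a two-compartment diffusion model (an axially symmetric "stick-like"
tensor, AD=1.8/RD=0, plus a "zeppelin", AD=1.5/RD=0.5 um^2/ms) with a
portion-specific volume fraction and fiber direction; the middle row of
portions contains two orthogonal crossing replicas of each compartment. Since
the 9 portions are internally constant, the demeaned voxel-by-measurement
matrix has rank exactly 9 - 1 = 8 - the ground-truth number of signal
components any denoiser should preserve.

Noise is added as iid Gaussian (or Rician) at a chosen SNR, and spatially
correlated noise is induced by zero-filling high-frequency k-space columns
(emulating partial-Fourier reconstruction) or by Gaussian smoothing. The
processing is applied identically to the noise-free signals so that an exact
post-processing ground truth is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Protocol",
    "CompartmentTensor",
    "PhantomDataset",
    "disperse_directions",
    "make_protocol",
    "compartment_signal",
    "build_phantom",
    "add_noise",
    "zerofill_correlate",
    "smooth_correlate",
    "sigma_prior_sweep",
    "make_experiment",
]

# Default volume fractions of compartment 1, by portion row (top, middle, bottom).
DEFAULT_FRACTIONS = np.array([
    [0.30, 0.35, 0.40],
    [0.60, 0.65, 0.70],
    [0.45, 0.50, 0.55],
])

# Per-portion fiber directions must be well separated: the smallest of the 8
# signal eigenvalues has to clear the Marchenko-Pastur noise band at the
# working SNR, otherwise weak signal components are indistinguishable from
# noise by construction. A deterministic electrostatic-repulsion set of 9
# unit vectors (one per portion) achieves this; see portion_directions().
DEFAULT_DIRECTION_SEED = 7

AD1, RD1 = 1.8, 0.0   # um^2/ms, compartment 1 (stick-like)
AD2, RD2 = 1.5, 0.5   # um^2/ms, compartment 2 (zeppelin)

GAMMA_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = GAMMA_FWHM * sigma


@dataclass(frozen=True)
class Protocol:
    """Diffusion acquisition protocol: b-values (ms/um^2) and unit b-vectors."""

    bvals: np.ndarray  # length N
    bvecs: np.ndarray  # N x 3, unit norm for b > 0, zeros for b = 0

    def __post_init__(self) -> None:
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs lengths differ")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("diffusion-weighted b-vectors must be unit norm")

    @property
    def n_measurements(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass(frozen=True)
class CompartmentTensor:
    """Axially symmetric diffusion tensor (axial/radial diffusivity, um^2/ms)."""

    ad: float
    rd: float
    direction: np.ndarray  # unit vector

    def __post_init__(self) -> None:
        if not self.ad >= self.rd >= 0:
            raise ValueError("require ad >= rd >= 0")

    @property
    def tensor(self) -> np.ndarray:
        n = np.asarray(self.direction, dtype=float)
        n = n / np.linalg.norm(n)
        return (self.ad - self.rd) * np.outer(n, n) + self.rd * np.eye(3)


@dataclass
class PhantomDataset:
    """A phantom realization: clean / noisy signals and their processed versions.

    ``processed_clean``/``processed_noisy`` equal their unprocessed
    counterparts when no correlation-inducing step was applied; the denoiser
    input is always ``processed_noisy`` and the matching ground truth
    ``processed_clean``.
    """

    clean: np.ndarray            # (X, Y, N), noise-free, S(b=0) = 1
    noisy: np.ndarray            # clean + noise
    processed_clean: np.ndarray
    processed_noisy: np.ndarray
    protocol: Protocol
    sigma_true: float            # SD of the added (pre-processing) noise
    fractions_grid: np.ndarray   # 3 x 3 compartment-1 fractions
    seed: Optional[int] = None

    def matrix(self, which: str = "processed_noisy") -> np.ndarray:
        """Voxels-by-measurements Casorati matrix of one signal array."""
        arr = getattr(self, which)
        return arr.reshape(-1, arr.shape[-1])


def disperse_directions(n: int, seed: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the hemisphere.

    A spherical Fibonacci lattice restricted to one hemisphere (gradient
    directions are antipodally equivalent) followed by a seeded random
    rotation; a reproducible stand-in for the repulsion-optimized gradient
    tables of real acquisitions.
    """
    i = np.arange(n)
    z = (i + 0.5) / n  # hemisphere: z in (0, 1)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    v = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    rot = _random_rotation(np.random.default_rng(seed))
    return v @ rot.T


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_protocol(n_b0: int = 20,
                  shells: Sequence[tuple[float, int]] = ((1.0, 30), (2.0, 30), (3.0, 30)),
                  seed: int = 0) -> Protocol:
    """Protocol of ``n_b0`` b=0 measurements plus multi-shell directions.

    The default reproduces the 110-measurement scheme: 20 b=0 plus shells at
    b = 1, 2, 3 ms/um^2 with 30 directions each. Directions are generated
    deterministically per shell (seed offset by the shell index).
    """
    if n_b0 < 0 or any(nd <= 0 or b <= 0 for b, nd in shells):
        raise ValueError("counts must be positive")
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for i, (b, n_dirs) in enumerate(shells):
        dirs = disperse_directions(n_dirs, seed=seed + 1000 * (i + 1))
        bvals.extend([float(b)] * n_dirs)
        bvecs.extend(dirs)
    return Protocol(bvals=np.asarray(bvals), bvecs=np.asarray(bvecs))


def compartment_signal(protocol: Protocol,
                       tensors: Sequence[tuple[float, CompartmentTensor]]) -> np.ndarray:
    """Multi-compartment signal S(b, g) = sum_j f_j exp(-b g^T D_j g).

    Volume fractions must sum to 1, so S(b=0) = 1.
    """
    fracs = np.array([f for f, _ in tensors], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1, got {fracs.sum()}")
    b = protocol.bvals
    g = protocol.bvecs
    signal = np.zeros(protocol.n_measurements)
    for f, t in tensors:
        adc = np.einsum("ij,jk,ik->i", g, t.tensor, g)
        signal += f * np.exp(-b * adc)
    return signal


def portion_directions(seed: int = DEFAULT_DIRECTION_SEED) -> np.ndarray:
    """Deterministic well-separated fiber directions, one per portion (9 x 3)."""
    return disperse_directions(9, seed=seed + 500)


def _perpendicular(d: np.ndarray) -> np.ndarray:
    # Deterministic unit vector orthogonal to d for the crossing portions.
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(d, ref)
    return v / np.linalg.norm(v)


def _portion_tensors(row: int, col: int, fractions: np.ndarray,
                     directions: np.ndarray) -> list[tuple[float, CompartmentTensor]]:
    f1 = float(fractions[row, col])
    d = directions[row * 3 + col]
    if row == 1:  # middle row: two orthogonal crossing replicas of each compartment
        d_perp = _perpendicular(d)
        return [
            (0.5 * f1, CompartmentTensor(AD1, RD1, d)),
            (0.5 * f1, CompartmentTensor(AD1, RD1, d_perp)),
            (0.5 * (1 - f1), CompartmentTensor(AD2, RD2, d)),
            (0.5 * (1 - f1), CompartmentTensor(AD2, RD2, d_perp)),
        ]
    return [
        (f1, CompartmentTensor(AD1, RD1, d)),
        (1 - f1, CompartmentTensor(AD2, RD2, d)),
    ]


def build_phantom(grid: int = 12,
                  fractions: Optional[np.ndarray] = None,
                  directions: Optional[np.ndarray] = None,
                  protocol: Optional[Protocol] = None,
                  seed: int = 0) -> PhantomDataset:
    """Noise-free phantom on a ``grid x grid`` voxel plane (grid multiple of 3).

    ``directions`` (9 x 3 unit vectors, one per portion, row-major) defaults
    to a fixed dispersed set. Returns a :class:`PhantomDataset` whose
    noisy/processed fields equal the clean signals; use :func:`add_noise` and
    the correlate functions (or :func:`make_experiment`) to corrupt it.
    """
    if grid % 3:
        raise ValueError("grid must be a multiple of 3 (3 x 3 portions)")
    fractions = DEFAULT_FRACTIONS if fractions is None else np.asarray(fractions, dtype=float)
    directions = portion_directions() if directions is None else np.asarray(directions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if protocol is None:
        protocol = make_protocol(seed=seed)
    p = grid // 3
    clean = np.empty((grid, grid, protocol.n_measurements))
    for row in range(3):
        for col in range(3):
            sig = compartment_signal(protocol, _portion_tensors(row, col, fractions, directions))
            clean[row * p:(row + 1) * p, col * p:(col + 1) * p, :] = sig
    return PhantomDataset(
        clean=clean, noisy=clean.copy(), processed_clean=clean.copy(),
        processed_noisy=clean.copy(), protocol=protocol, sigma_true=0.0,
        fractions_grid=fractions, seed=seed,
    )


def add_noise(dataset: PhantomDataset, sigma: float, model: str = "gaussian",
              seed: int = 0) -> PhantomDataset:
    """Corrupt the clean signals with iid Gaussian or Rician noise of SD ``sigma``.

    Rician noise is the magnitude of the signal plus a complex Gaussian with
    independent real and imaginary parts of variance sigma^2. A fixed seed
    reproduces the realization bit-identically.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        noisy = dataset.clean + sigma * rng.standard_normal(dataset.clean.shape)
    elif model == "rician":
        re = dataset.clean + sigma * rng.standard_normal(dataset.clean.shape)
        im = sigma * rng.standard_normal(dataset.clean.shape)
        noisy = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model '{model}'")
    return replace(dataset, noisy=noisy, processed_noisy=noisy.copy(),
                   processed_clean=dataset.clean.copy(), sigma_true=float(sigma), seed=seed)


def zerofill_correlate(images: np.ndarray, n_zero_cols: int) -> np.ndarray:
    """Induce spatially correlated noise by zero-filling k-space columns.

    Per measurement volume: 2D FFT over the first two axes, the
    ``n_zero_cols`` highest-frequency columns set to zero (Nyquist first,
    then +/- frequency pairs, so the zeroed set is conjugate-closed and the
    operation is an orthogonal projection on real images), inverse FFT, real
    part. Zeroing c of X columns therefore scales white-noise variance by
    exactly (X - c)/X. ``n_zero_cols = 0`` is the identity up to FFT
    round-off.
    """
    images = np.asarray(images, dtype=float)
    ncols = images.shape[1]
    if n_zero_cols < 0 or n_zero_cols >= ncols:
        raise ValueError("n_zero_cols must be in [0, number of columns)")
    if n_zero_cols == 0:
        return images.copy()
    freqs = np.fft.fftfreq(ncols) * ncols
    order = np.lexsort((freqs, -np.abs(freqs)))  # highest |k| first, -k before +k
    k = np.fft.fft2(images, axes=(0, 1))
    k[:, order[:n_zero_cols], ...] = 0.0
    return np.real(np.fft.ifft2(k, axes=(0, 1)))


def smooth_correlate(images: np.ndarray, fwhm: float) -> np.ndarray:
    """Induce spatially correlated noise by in-plane Gaussian smoothing.

    ``fwhm`` is in voxels; 0 is the identity. Reflective boundary handling.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    images = np.asarray(images, dtype=float)
    if fwhm == 0:
        return images.copy()
    sig = fwhm / GAMMA_FWHM
    ndim = images.ndim
    sigma = (sig, sig) + (0,) * (ndim - 2)
    return gaussian_filter(images, sigma=sigma, mode="reflect")


def sigma_prior_sweep(true_sigma2: float, factors: Sequence[float]) -> np.ndarray:
    """Perturbed priors ``true_sigma2 * factor`` for robustness curves."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    return true_sigma2 * factors


def make_experiment(seed: int, snr: float = 30.0, grid: int = 12,
                    correlate: Optional[str] = None, n_zero_cols: Optional[int] = None,
                    fwhm: float = 2.0, noise_model: str = "gaussian",
                    protocol: Optional[Protocol] = None) -> PhantomDataset:
    """One full phantom realization under the standard study conditions.

    ``correlate=None`` is the uncorrelated-noise setting; ``"zerofill"``
    zero-fills high-frequency k-space columns (default 3 for a 12-voxel grid,
    scaled as grid//4 otherwise) and ``"smooth"`` applies Gaussian smoothing.
    Processing is applied identically to clean and noisy signals. The noise SD
    is 1/snr since the phantom's b=0 signal is normalized to 1.
    """
    ds = build_phantom(grid=grid, protocol=protocol, seed=0)  # geometry fixed; seed drives noise
    ds = add_noise(ds, sigma=1.0 / snr, model=noise_model, seed=seed)
    if correlate is None:
        return ds
    if correlate == "zerofill":
        n_cols = grid // 4 if n_zero_cols is None else n_zero_cols
        proc_clean = zerofill_correlate(ds.clean, n_cols)
        proc_noisy = zerofill_correlate(ds.noisy, n_cols)
    elif correlate == "smooth":
        proc_clean = smooth_correlate(ds.clean, fwhm)
        proc_noisy = smooth_correlate(ds.noisy, fwhm)
    else:
        raise ValueError(f"unknown correlate option '{correlate}'")
    return replace(ds, processed_clean=proc_clean, processed_noisy=proc_noisy)
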