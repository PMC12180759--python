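"""Denoising performance metrics: residuals, residual normality, eigenvalue
spectrum ensembles, RMSE against ground truth, and component-count summaries.

Because the ground truth of the synthetic phantom is known exactly, denoising
quality is assessed directly on signals (RMSE, residual Gaussianity) and on
the number of preserved principal components, rather than through downstream
model fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .mp_theory import MPParams

__all__ = [
    "SpectrumEnsemble",
    "QQResult",
    "residuals",
    "qq_gaussian",
    "spectrum_ensemble",
    "rmse_map",
    "ncomp_histogram",
]


@dataclass
class SpectrumEnsemble:
    """Noise eigenvalues pooled over repeated noise realizations.

    ``reference`` is the MP law with matching aspect ratio whose variance
    equals the mean of the pooled eigenvalues, the natural theoretical
    comparison: under uncorrelated noise the pooled spectrum should fill the
    reference support, while correlated noise widens it beyond lambda_plus.
    """

    eigenvalue_samples: np.ndarray
    n_reps: int
    reference: MPParams


@dataclass
class QQResult:
    """Quantile-quantile comparison of a residual sample against a Gaussian."""

    sample_quantiles: np.ndarray
    theoretical_quantiles: np.ndarray
    correlation: float


def residuals(denoised: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Elementwise ``denoised - raw`` (what the denoiser removed, negated)."""
    denoised, raw = np.asarray(denoised), np.asarray(raw)
    if denoised.shape != raw.shape:
        raise ValueError(f"shape mismatch: {denoised.shape} vs {raw.shape}")
    return denoised - raw


def qq_gaussian(residual_sample: np.ndarray) -> QQResult:
    """Standardized residual quantiles against standard-normal quantiles.

    Uses plotting positions (i - 0.5)/n. The Pearson correlation of the
    paired quantiles summarizes Gaussianity (1 = perfectly Gaussian shape);
    the standardization makes the result location/scale invariant.
    """
    x = np.asarray(residual_sample, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 residual samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("residual sample has zero variance (degenerate denoising)")
    z = np.sort((x - x.mean()) / sd)
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    theo = stats.norm.ppf(probs)
    r = float(np.corrcoef(z, theo)[0, 1])
    return QQResult(sample_quantiles=z, theoretical_quantiles=theo, correlation=r)


def spectrum_ensemble(spectrum_fn: Callable[[int], tuple[np.ndarray, int]],
                      n_reps: int, gamma: float, seed: int = 0) -> SpectrumEnsemble:
    """Pool noise-classified eigenvalues over repeated realizations.

    ``spectrum_fn(rep_seed)`` must return ``(eigenvalues_ascending, C)`` for
    one realization; the C smallest eigenvalues are pooled. The reference MP
    law uses the supplied aspect ratio ``gamma`` with its variance matched to
    the pooled eigenvalue mean.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_reps):
        lam, C = spectrum_fn(int(rng.integers(0, 2**31 - 1)))
        pooled.append(np.asarray(lam)[:C])
    samples = np.concatenate(pooled) if pooled else np.empty(0)
    sigma2 = float(samples.mean()) if samples.size else 1e-300
    return SpectrumEnsemble(eigenvalue_samples=samples, n_reps=n_reps,
                            reference=MPParams(sigma2=max(sigma2, 1e-300), gamma=gamma))


def rmse_map(estimate: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Root-mean-square error per voxel (over measurements) and globally."""
    estimate, truth = np.asarray(estimate, dtype=float), np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimate.shape} vs {truth.shape}")
    se = (estimate - truth) ** 2
    per_voxel = np.sqrt(se.mean(axis=-1))
    return per_voxel, float(np.sqrt(se.mean()))


def ncomp_histogram(ncomp_map: np.ndarray,
                    mask: Optional[np.ndarray] = None) -> dict[int, float]:
    """Relative frequency of preserved-component counts over window centers.

    Entries of -1 (voxels that were never a window center) are ignored.
    """
    vals = np.asarray(ncomp_map).ravel()
    if mask is not None:
        vals = np.asarray(ncomp_map)[np.asarray(mask, dtype=bool)].ravel()
    vals = vals[vals >= 0]
    if vals.size == 0:
        raise ValueError("no window-center values to histogram (empty mask?)")
    uniq, counts = np.unique(vals.astype(int), return_counts=True)
    total = counts.sum()
    return {int(u): float(c) / total for u, c in zip(uniq, counts)}
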