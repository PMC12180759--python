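"""Noise-variance priors from repeated measurements.

The prior-based classifiers (GPCA, TPCA) need an estimate of the effective
noise variance after image reconstruction. Rather than assuming how noise is
distributed across space, the map is estimated voxel-by-voxel as the unbiased
sample variance across r repetitions of an identical acquisition (for
diffusion MRI, the repeated b=0 volumes), then condensed per sliding window
by the median — robust to voxels corrupted by motion, pulsation or drift
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NoisePriorMap",
    "variance_from_repeats",
    "window_median_sigma2",
    "global_mean_sigma2",
]


@dataclass
class NoisePriorMap:
    """Voxelwise noise-variance prior estimated from repeated acquisitions."""

    sigma2: np.ndarray  # 3D map, signal-units squared, >= 0
    r: int  # number of repetitions used
    source_indices: Optional[np.ndarray] = None  # which volumes entered

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("need at least 2 repetitions")
        if np.any(self.sigma2 < 0):
            raise ValueError("variance map must be non-negative")


def variance_from_repeats(b0_stack: np.ndarray,
                          source_indices: Optional[Sequence[int]] = None) -> NoisePriorMap:
    """Unbiased per-voxel sample variance across repeated volumes.

    Parameters
    ----------
    b0_stack : ndarray
        Stack of r repeated volumes along the LAST axis, e.g. shape
        (x, y, z, r) or (x, y, r).

    Returns the variance ``sum_i (S_i - S_bar)^2 / (r - 1)`` per voxel.
    """
    b0_stack = np.asarray(b0_stack, dtype=float)
    r = b0_stack.shape[-1]
    if r < 2:
        raise ValueError(f"need at least 2 repetitions, got {r}")
    sigma2 = b0_stack.var(axis=-1, ddof=1)
    idx = None if source_indices is None else np.asarray(source_indices)
    return NoisePriorMap(sigma2=sigma2, r=r, source_indices=idx)


def window_median_sigma2(noise_map: NoisePriorMap, window: Sequence[int],
                         center: Sequence[int],
                         mask: Optional[np.ndarray] = None) -> float:
    """Effective prior for one window: median of the in-window variance values.

    The window is clamped to stay inside the map; with an even number of
    values the median is the mean of the middle two. Background voxels are
    included unless excluded through ``mask``.
    """
    sig = noise_map.sigma2
    window = tuple(int(w) for w in window)
    center = tuple(int(c) for c in center)
    if len(window) != sig.ndim or len(center) != sig.ndim:
        raise ValueError("window/center dimensionality must match the map")
    sl = []
    for dim, w, c in zip(sig.shape, window, center):
        if w > dim:
            raise ValueError(f"window extent {w} exceeds map extent {dim}")
        start = min(max(c - w // 2, 0), dim - w)
        sl.append(slice(start, start + w))
    vals = sig[tuple(sl)]
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)[tuple(sl)]]
        if vals.size == 0:
            raise ValueError("window is empty after masking")
    return float(np.median(vals))


def global_mean_sigma2(noise_map: NoisePriorMap,
                       mask: Optional[np.ndarray] = None) -> float:
    """Voxel-averaged variance, the scalar prior used in uniform-noise settings."""
    sig = noise_map.sigma2
    if mask is not None:
        sig = sig[np.asarray(mask, dtype=bool)]
    return float(np.mean(sig))
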