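"""Marchenko-Pastur (MP) distribution machinery.

For an M x N matrix (M >= N) filled with iid zero-mean noise of variance
``sigma2``, the eigenvalues of the sample covariance ``X.T @ X / M`` converge,
as M, N -> infinity with aspect ratio ``gamma = N/M`` fixed, to the MP density

    p(lam) = sqrt((lam_plus - lam)(lam - lam_minus)) / (2 pi gamma lam sigma2)

supported on ``[lam_minus, lam_plus]`` with edges

    lam_pm = sigma2 * (1 +/- sqrt(gamma))**2

so the support width is exactly ``4 sqrt(gamma) sigma2``.  Inverting the width
relation gives the bandwidth-based variance estimator used by the
moment-matching classifier: ``sigma2_hat = (lam_max - lam_min) / (4 sqrt(gamma_c))``
with ``gamma_c = C/M`` for a candidate noise subset of size C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MPParams", "MPBounds", "mp_bounds", "mp_pdf", "sigma2_from_width"]


@dataclass(frozen=True)
class MPParams:
    """Parameters of a Marchenko-Pastur law.

    Parameters
    ----------
    sigma2 : float
        Noise variance, in squared signal units. Must be non-negative.
    gamma : float
        Aspect ratio N/M of the underlying noise matrix, with M >= N so
        that 0 < gamma <= 1. Callers holding an M < N matrix must
        transpose before computing gamma.
    """

    sigma2: float
    gamma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise ValueError(f"sigma2 must be finite and >= 0, got {self.sigma2}")
        if not np.isfinite(self.gamma) or not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")


@dataclass(frozen=True)
class MPBounds:
    """Support edges [lambda_minus, lambda_plus] of an MP law."""

    lambda_minus: float
    lambda_plus: float

    @property
    def width(self) -> float:
        return self.lambda_plus - self.lambda_minus


def mp_bounds(params: MPParams) -> MPBounds:
    """Support edges ``sigma2 * (1 +/- sqrt(gamma))**2`` of the MP law."""
    sq = np.sqrt(params.gamma)
    return MPBounds(
        lambda_minus=params.sigma2 * (1.0 - sq) ** 2,
        lambda_plus=params.sigma2 * (1.0 + sq) ** 2,
    )


def mp_pdf(lam, params: MPParams):
    """Marchenko-Pastur probability density evaluated at eigenvalue(s) ``lam``.

    Returns 0 outside the support ``(lambda_minus, lambda_plus)``. Accepts
    scalars or arrays; negative eigenvalues are a domain error.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("eigenvalues must be non-negative")
    if params.sigma2 == 0:
        # Degenerate point mass at 0; density undefined, report 0 everywhere.
        return np.zeros_like(lam_arr) if lam_arr.ndim else 0.0
    b = mp_bounds(params)
    inside = (lam_arr > b.lambda_minus) & (lam_arr < b.lambda_plus)
    dens = np.zeros_like(lam_arr, dtype=float)
    lam_in = lam_arr[inside]
    dens[inside] = np.sqrt((b.lambda_plus - lam_in) * (lam_in - b.lambda_minus)) / (
        2.0 * np.pi * params.gamma * lam_in * params.sigma2
    )
    return dens if lam_arr.ndim else float(dens)


def sigma2_from_width(lambda_max: float, lambda_min: float, gamma_c: float) -> float:
    """Bandwidth-based noise variance estimate ``(lam_max - lam_min) / (4 sqrt(gamma_c))``.

    ``gamma_c`` is C/M for the C smallest eigenvalues under consideration.
    """
    if gamma_c <= 0:
        raise ValueError(f"gamma_c must be positive, got {gamma_c}")
    if lambda_min < 0 or lambda_max < lambda_min:
        raise ValueError("require lambda_max >= lambda_min >= 0")
    return (lambda_max - lambda_min) / (4.0 * np.sqrt(gamma_c))
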