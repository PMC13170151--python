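"""Spherical-spline surface Laplacian (current source density, CSD).

Scalp potentials are interpolated with spherical splines of stiffness
order ``m`` and the surface Laplacian of the interpolant is evaluated at
the electrodes.  The two kernels are Legendre series over inter-electrode
angles theta_ij:

    G[i, j] = sum_{n=1}^{N} (2n+1) / (n(n+1))^m     * P_n(cos theta_ij) / (4 pi)
    H[i, j] = sum_{n=1}^{N} (2n+1) / (n(n+1))^(m-1) * P_n(cos theta_ij) / (4 pi)

The transform solves the ridge-regularized spline system (G + lambda I)
under the standard constraint that the spline coefficients sum to zero,
then emits the H-weighted coefficients.  On the unit sphere the output
units are arbitrary; magnitude-squared coherence downstream is invariant
to that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import legval


class CsdError(ValueError):
    pass


@dataclass
class SplineMatrices:
    G: np.ndarray
    H: np.ndarray
    m: int
    n_terms: int


def _legendre_series(cosang: np.ndarray, exponent: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** exponent / (4 * np.pi)
    return legval(cosang, coef)


def build_spline_matrices(montage, m: int = 4, n_terms: int = 50) -> SplineMatrices:
    """Spline kernels G and H for a montage (depends only on angles)."""
    if m < 2:
        raise CsdError("interpolation constant m must be >= 2")
    if n_terms < 7:
        raise CsdError("n_terms too small for a stable series")
    coords = np.asarray(montage.coords, float)
    cosang = np.clip(coords @ coords.T, -1.0, 1.0)
    off = cosang - np.eye(len(coords))
    if np.any(off >= 1.0 - 1e-12):
        i, j = np.argwhere(off >= 1.0 - 1e-12)[0]
        raise CsdError(
            f"coincident electrodes: {montage.channels[i]} and {montage.channels[j]}"
        )
    G = _legendre_series(cosang, m, n_terms)
    H = _legendre_series(cosang, m - 1, n_terms)
    return SplineMatrices(G=G, H=H, m=m, n_terms=n_terms)


def csd_transform(splines: SplineMatrices, lam: float = 1e-5) -> np.ndarray:
    """Dense linear map M with csd = M @ potentials (channels x channels).

    Derived from the constrained system

        (G + lam I) c + c0 * 1 = x,   sum(c) = 0

    via its Schur complement: with Gi = (G + lam I)^-1,
    c = Gi x - Gi 1 (1' Gi x) / (1' Gi 1) and M = H @ (that map).
    """
    d = splines.G.shape[0]
    Glam = splines.G + lam * np.eye(d)
    try:
        Gi = np.linalg.inv(Glam)
    except np.linalg.LinAlgError as err:
        raise CsdError(f"singular regularized spline system: {err}") from err
    g1 = Gi @ np.ones(d)
    denom = g1.sum()
    if abs(denom) < 1e-300:
        raise CsdError("singular constrained system (1' Gi 1 = 0)")
    B = Gi - np.outer(g1, g1) / denom
    return splines.H @ B


def apply_csd(data: np.ndarray, splines: SplineMatrices, lam: float = 1e-5) -> np.ndarray:
    """Apply the surface Laplacian to (channels x samples) data."""
    data = np.asarray(data, float)
    if data.shape[0] != splines.G.shape[0]:
        raise CsdError(
            f"data has {data.shape[0]} channels, spline matrices expect {splines.G.shape[0]}"
        )
    return csd_transform(splines, lam) @ data
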