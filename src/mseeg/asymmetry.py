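"""Directional brain symmetry index (dirBSI).

The dirBSI summarizes hemispheric lateralization as a single signed ratio

    dirBSI = sum_{pairs, bins} (R - L) / sum_{pairs, bins} (R + L)

where R and L are spectral power (default) or amplitude of the right- and
left-hemisphere members of each homologous electrode pair, evaluated at
integer-Hz bins 4..16.  Values lie in [-1, 1]: positive means
right-hemisphere (after flipping: ipsilesional) predominance, negative
left-hemisphere predominance, 0 symmetry.  Band-restricted variants sum
over the band's integer bins only (theta 4-6, alpha 7-11, beta1 12-15,
half-open upper edges); the full-range variant uses all bins 4..16.

Computed on average-referenced, flipped, non-Laplacian signals -- the same
path as the PSD features, not the CSD connectivity path.
"""

from __future__ import annotations

import numpy as np

from .montage import Montage
from .spectral import BANDS, BandDef, welch_psd


class AsymmetryError(ValueError):
    pass


def pairwise_spectra(
    data: np.ndarray,
    channels: list[str],
    montage: Montage,
    fs: float,
    freq_range: tuple[float, float] = (4.0, 16.0),
    resolution: float = 1.0,
    quantity: str = "power",
    window_s: float = 2.0,
    step_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair spectral matrices R, L (n_pairs x n_bins) plus bin freqs.

    Spectra are Welch estimates evaluated at the integer-Hz grid
    ``freq_range[0] .. freq_range[1]`` (inclusive) with the given
    resolution; ``quantity`` selects power (uV^2/Hz) or amplitude.
    """
    if quantity not in ("power", "amplitude"):
        raise AsymmetryError("quantity must be 'power' or 'amplitude'")
    index = {c: i for i, c in enumerate(channels)}
    missing = [c for p in montage.pairs for c in p if c not in index]
    if missing:
        raise AsymmetryError(f"pair channels missing from data: {sorted(set(missing))}")
    li = np.array([index[l] for l, _ in montage.pairs])
    ri = np.array([index[r] for _, r in montage.pairs])
    data = np.asarray(data, float)
    est = welch_psd(data[np.concatenate([ri, li])], fs, window_s, step_s)
    bins = np.arange(freq_range[0], freq_range[1] + resolution / 2, resolution)
    cols = []
    for f in bins:
        j = int(np.argmin(np.abs(est.freqs - f)))
        if abs(est.freqs[j] - f) > 1e-6:
            raise AsymmetryError(f"frequency grid does not contain {f} Hz")
        cols.append(j)
    spec = est.psd[:, cols]
    if quantity == "amplitude":
        spec = np.sqrt(spec)
    n = len(montage.pairs)
    return spec[:n], spec[n:], bins  # R, L


def dirbsi(R: np.ndarray, L: np.ndarray, bins: np.ndarray | None = None,
           band: BandDef | None = None) -> float:
    """Signed symmetry ratio over pair x bin cells, optionally band-restricted."""
    R = np.asarray(R, float)
    L = np.asarray(L, float)
    if R.shape != L.shape:
        raise AsymmetryError("R and L must have the same shape")
    if np.any(R < 0) or np.any(L < 0):
        raise AsymmetryError("spectral values must be nonnegative")
    if band is not None:
        if bins is None:
            raise AsymmetryError("band restriction requires the bin frequencies")
        mask = (bins >= band.lo) & (bins < band.hi)
        if not mask.any():
            raise AsymmetryError(f"no bins inside band {band.name}")
        R, L = R[:, mask], L[:, mask]
    denom = np.sum(R + L)
    if denom == 0:
        raise AsymmetryError("all-zero spectra: dirBSI undefined")
    return float(np.sum(R - L) / denom)


def subject_dirbsi(
    data: np.ndarray,
    channels: list[str],
    montage: Montage,
    fs: float,
    quantity: str = "power",
) -> dict[str, float]:
    """Per-band dirBSI plus the full-range (4-16 Hz) variant."""
    R, L, bins = pairwise_spectra(data, channels, montage, fs, quantity=quantity)
    out = {name: dirbsi(R, L, bins, band) for name, band in BANDS.items()}
    out["full"] = dirbsi(R, L)
    return out
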