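"""ROI-pair magnitude-squared coherence on surface-Laplacian signals.

Coherence between regions X and Y is

    C_XY(f) = |P_XY(f)|^2 / (P_XX(f) * P_YY(f))

with Welch auto- and cross-spectra sharing the segmentation of the PSD
module (2-s Hamming windows, 1-s steps).  The band summary is the mean of
per-bin coherence over the band's bins (half-open [lo, hi)).  With K
averaged windows the estimator has a positive bias of order 1/K under
independence, so a minimum of 8 windows is enforced and fewer than 20
triggers a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .spectral import BAND_ORDER, BANDS, BandDef

MIN_WINDOWS = 8
WARN_WINDOWS = 20


class ConnectivityError(ValueError):
    pass


@dataclass
class CrossSpectra:
    freqs: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pxy: np.ndarray  # complex
    n_windows: int


def cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    step_s: float = 1.0,
) -> CrossSpectra:
    """Welch auto- and cross-spectra of two equal-length series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ConnectivityError(f"length mismatch: {x.shape} vs {y.shape}")
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ConnectivityError("series shorter than one window")
    noverlap = nperseg - int(round(step_s * fs))
    kw = dict(fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
              detrend=False, scaling="density")
    freqs, pxx = signal.welch(x, **kw)
    _, pyy = signal.welch(y, **kw)
    _, pxy = signal.csd(x, y, **kw)
    n_windows = (x.size - nperseg) // int(round(step_s * fs)) + 1
    if n_windows < MIN_WINDOWS:
        raise ConnectivityError(
            f"only {n_windows} Welch windows; coherence needs >= {MIN_WINDOWS}"
        )
    if n_windows < WARN_WINDOWS:
        warnings.warn(
            f"coherence from {n_windows} windows has bias ~1/K = {1 / n_windows:.3f}",
            stacklevel=2,
        )
    return CrossSpectra(freqs, pxx, pyy, pxy, n_windows)


def msc(spec: CrossSpectra, band: BandDef) -> float:
    """Band-mean magnitude-squared coherence over [lo, hi) bins."""
    mask = (spec.freqs >= band.lo) & (spec.freqs < band.hi)
    if not mask.any():
        raise ConnectivityError(f"no frequency bins in band {band.name}")
    pxx, pyy = spec.pxx[mask], spec.pyy[mask]
    if np.any(pxx <= 0) or np.any(pyy <= 0):
        raise ConnectivityError("zero auto-spectrum bin inside band")
    c = np.abs(spec.pxy[mask]) ** 2 / (pxx * pyy)
    return float(np.mean(c))


def roi_coherence_table(
    roi_series: dict[str, np.ndarray],
    fs: float,
    bands: dict[str, BandDef] | None = None,
    window_s: float = 2.0,
    step_s: float = 1.0,
) -> pd.DataFrame:
    """All unordered ROI-pair x band coherences from named ROI series.

    ``roi_series`` maps ROI id to a surface-Laplacian, ROI-averaged series.
    Six ROIs give 15 unique pairs; with three bands the table has 45 rows.
    """
    bands = bands or BANDS
    rois = list(roi_series)
    rows = []
    for a, b in itertools.combinations(rois, 2):
        spec = cross_spectra(roi_series[a], roi_series[b], fs, window_s, step_s)
        for name in BAND_ORDER:
            if name not in bands:
                continue
            rows.append(
                {
                    "roi_a": a,
                    "roi_b": b,
                    "band": name,
                    "coherence": msc(spec, bands[name]),
                    "n_windows": spec.n_windows,
                }
            )
    return pd.DataFrame(rows)


def lookup(table: pd.DataFrame, roi_a: str, roi_b: str, band: str) -> float:
    """Symmetric lookup of a coherence entry."""
    m = (
        ((table.roi_a == roi_a) & (table.roi_b == roi_b))
        | ((table.roi_a == roi_b) & (table.roi_b == roi_a))
    ) & (table.band == band)
    hit = table[m]
    if hit.empty:
        raise ConnectivityError(f"no entry for ({roi_a}, {roi_b}, {band})")
    return float(hit.coherence.iloc[0])
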