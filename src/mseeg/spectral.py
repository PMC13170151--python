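"""Welch spectral estimation, dB transform, band power, and peak alpha frequency.

All spectra use the same segmentation everywhere in the pipeline: 2-s
Hamming windows advanced in 1-s steps, one-sided density normalization
(integral over frequency approximates variance).  Detrending is disabled
so that spectra are exactly linear in the input and algebraic identities
(scaling, window concatenation) hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise SpectralError(f"band {self.name}: lo must be < hi")


#: Analysis bands.  Shared edges (7, 12 Hz) are assigned half-open [lo, hi)
#: wherever discrete bins are selected, keeping the three bands disjoint.
BANDS: dict[str, BandDef] = {
    "theta": BandDef("theta", 4.0, 7.0),
    "alpha": BandDef("alpha", 7.0, 12.0),
    "beta1": BandDef("beta1", 12.0, 16.0),
}
BAND_ORDER = ("theta", "alpha", "beta1")


@dataclass
class SpectralEstimate:
    freqs: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray    # linear uV^2/Hz; last axis is frequency
    n_windows: int


def welch_psd(
    series: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    step_s: float = 1.0,
    taper: str = "hamming",
) -> SpectralEstimate:
    """Welch averaged-periodogram PSD of one series (or a stack of series)."""
    series = np.asarray(series, float)
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    n = series.shape[-1]
    if n < nperseg:
        raise SpectralError(f"series length {n} shorter than one {window_s}-s window")
    freqs, psd = signal.welch(
        series,
        fs=fs,
        window=taper,
        nperseg=nperseg,
        noverlap=nperseg - step,
        detrend=False,
        scaling="density",
        average="mean",
    )
    n_windows = (n - nperseg) // step + 1
    return SpectralEstimate(freqs=freqs, psd=psd, n_windows=n_windows)


def to_db(x):
    """Linear power to decibels: 10 * log10(x).  Non-positive input raises."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise SpectralError("dB transform requires strictly positive power")
    out = 10.0 * np.log10(x)
    return float(out) if out.ndim == 0 else out


def band_power(est: SpectralEstimate, band: BandDef, in_db: bool = False) -> float:
    """Trapezoidal integral of the linear PSD over [band.lo, band.hi].

    Trapezoid integrals over contiguous bands sharing an endpoint are
    additive, so theta + alpha + beta1 equals the integral over [4, 16].
    """
    mask = (est.freqs >= band.lo) & (est.freqs <= band.hi)
    if mask.sum() < 2:
        raise SpectralError(f"band {band.name} covers fewer than two grid points")
    p = float(np.trapezoid(est.psd[..., mask], est.freqs[mask], axis=-1))
    return to_db(p) if in_db else p


@dataclass
class PafResult:
    paf_hz: float
    no_peak: bool  # maximum on a range boundary with a monotone spectrum


def peak_alpha_frequency(est: SpectralEstimate, lo: float = 7.0, hi: float = 12.0) -> PafResult:
    """Frequency of the maximum PSD bin within [lo, hi].

    Ties break toward the lower frequency.  If the maximum sits on a range
    boundary and the spectrum is monotone across the range, there is no
    true peak and ``no_peak`` is flagged (value still reported).
    """
    mask = (est.freqs >= lo) & (est.freqs <= hi)
    if not mask.any():
        raise SpectralError("alpha range not covered by the frequency grid")
    f = est.freqs[mask]
    p = np.asarray(est.psd)[..., mask]
    if p.ndim != 1:
        raise SpectralError("peak_alpha_frequency expects a single spectrum")
    i = int(np.argmax(p))  # argmax returns the first (lowest-frequency) maximum
    d = np.diff(p)
    monotone = bool(np.all(d <= 0) or np.all(d >= 0))
    no_peak = monotone and (i == 0 or i == len(f) - 1)
    return PafResult(paf_hz=float(f[i]), no_peak=no_peak)
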