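"""Fixed preprocessing chain for resting-state EEG.

Order is fixed and recorded in segment provenance:

    50 Hz notch -> 0.5-30 Hz band-pass (4th-order Butterworth, zero-phase)
    -> threshold-clean 90-s segment extraction -> common average reference
    -> hemisphere flip (left-lesion subjects only)

Both filters are applied forward-backward (zero phase), standard for
offline spectral analysis.  The +-100 uV artifact criterion is applied to
the filtered (analysis-band) signal in non-overlapping 2-s windows, the
same granularity as the Welch segmentation.  Common average and flip
commute (the flip is a channel permutation, so it preserves the per-sample
mean), which is asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import Montage


class PreprocessError(ValueError):
    pass


@dataclass
class Recording:
    """Multichannel time series in uV with subject metadata."""

    data: np.ndarray          # (n_channels, n_samples)
    fs: float
    channels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[0] != len(self.channels):
            raise PreprocessError("data rows must match channel list")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("non-finite samples in recording")
        if self.fs < 2 * 16:
            raise PreprocessError("sampling rate must exceed twice the top analysis frequency")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Segment(Recording):
    provenance: dict = field(default_factory=dict)


def filter_chain(
    rec: Recording,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.5, 30.0),
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase notch then Butterworth band-pass; length preserved."""
    lo, hi = band
    nyq = rec.fs / 2
    if not (0 < lo < hi < nyq):
        raise PreprocessError(f"band {band} must lie inside (0, {nyq})")
    data = rec.data
    if notch_hz is not None and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    meta = dict(rec.meta)
    meta.setdefault("steps", []).append(
        {"step": "filter_chain", "notch_hz": notch_hz, "band": list(band),
         "order": order, "notch_q": notch_q, "phase": "zero (forward-backward)"}
    )
    return Recording(data, rec.fs, list(rec.channels), meta)


def extract_clean_segment(
    rec: Recording,
    threshold_uv: float = 100.0,
    target_s: float = 90.0,
    window_s: float = 2.0,
) -> Segment:
    """Earliest threshold-clean windows concatenated to exactly ``target_s``.

    The recording is tiled into consecutive non-overlapping windows; any
    window containing a sample with |value| > threshold on any channel is
    discarded.  Raises when fewer than ``target_s`` clean seconds survive,
    reporting what was available.
    """
    if rec.duration_s < target_s:
        raise PreprocessError(
            f"recording is {rec.duration_s:.1f} s, shorter than target {target_s} s"
        )
    win = int(round(window_s * rec.fs))
    n_win = rec.data.shape[1] // win
    needed = int(round(target_s / window_s))
    if needed * window_s != target_s:
        raise PreprocessError("target_s must be a multiple of window_s")
    keep = []
    for w in range(n_win):
        chunk = rec.data[:, w * win:(w + 1) * win]
        if np.max(np.abs(chunk)) <= threshold_uv:
            keep.append(w)
        if len(keep) == needed:
            break
    if len(keep) < needed:
        raise PreprocessError(
            f"insufficient clean data: {len(keep) * window_s:.0f} clean seconds "
            f"available, {target_s:.0f} required (threshold {threshold_uv} uV)"
        )
    data = np.concatenate([rec.data[:, w * win:(w + 1) * win] for w in keep], axis=1)
    prov = {"source_windows": keep, "window_s": window_s,
            "threshold_uv": threshold_uv, "target_s": target_s}
    return Segment(data, rec.fs, list(rec.channels), dict(rec.meta), provenance=prov)


def common_average(seg: Segment) -> Segment:
    """Subtract the per-sample mean across channels (idempotent)."""
    if seg.data.shape[0] < 2:
        raise PreprocessError("common average needs at least 2 channels")
    data = seg.data - seg.data.mean(axis=0, keepdims=True)
    out = replace(seg, data=data, meta=dict(seg.meta),
                  provenance=dict(seg.provenance))
    out.meta.setdefault("steps", []).append({"step": "common_average"})
    return out


def flip_hemispheres(seg: Segment, lesion_side: str | None, montage: Montage) -> Segment:
    """Mirror left-lesion subjects onto the right-hemisphere lesion model.

    Channel rows are permuted by the homologous pair map (midline fixed)
    for ``lesion_side == 'left'``; 'right' and 'none' are the identity.
    """
    if lesion_side not in ("left", "right", "none"):
        raise PreprocessError(
            f"lesion side must be 'left', 'right' or 'none'; got {lesion_side!r}"
        )
    flipped = lesion_side == "left"
    if flipped:
        if list(seg.channels) != list(montage.channels):
            raise PreprocessError("segment channels must match montage for flipping")
        data = seg.data[montage.flip_permutation()]
    else:
        data = seg.data
    out = replace(seg, data=data, meta=dict(seg.meta), provenance=dict(seg.provenance))
    out.meta["flip_applied"] = flipped
    return out


def spectral_outlier_windows(
    rec: Recording, window_s: float = 2.0, n_robust_sd: float = 5.0
) -> list[int]:
    """Optional flag for windows with abnormal broadband power (off by default).

    A window is flagged when its mean channel power exceeds the recording's
    median window power by ``n_robust_sd`` robust (MAD-based) SDs.
    """
    win = int(round(window_s * rec.fs))
    n_win = rec.data.shape[1] // win
    power = np.array([
        float(np.mean(rec.data[:, w * win:(w + 1) * win] ** 2)) for w in range(n_win)
    ])
    med = np.median(power)
    mad = np.median(np.abs(power - med)) * 1.4826
    if mad == 0:
        return []
    return [w for w in range(n_win) if power[w] > med + n_robust_sd * mad]
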