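"""Electrode geometry, regions of interest, and homologous left-right pairs.

The montage is the geometric backbone of the pipeline: unit-sphere electrode
positions drive the spherical-spline Laplacian, ROI membership defines the
six averaged regional signals (F, AM, C, UM, P, O), and the sagittal
mirror-pair map supports both the hemisphere-flipping step and the
directional brain symmetry index.

Coordinate convention follows the head frame used by MNE-Python: +x points
to the subject's right, +y anterior, +z superior.  The sagittal plane is
x = 0; a channel's mirror image is obtained by negating x.  All positions
are normalized to unit radius after centering -- coherence and the symmetry
index are scale-invariant, so the head radius is irrelevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ROI_IDS = ("F", "AM", "C", "UM", "P", "O")

#: ROI electrode lists for the 129-channel geodesic net (E1..E128 + Cz).
#: AM/UM denote the ipsi-/contralesional motor regions *after* flipping;
#: before flipping they are fixed electrode sets like any other ROI.
GEODESIC_ROIS: dict[str, tuple[str, ...]] = {
    "F": ("E4", "E5", "E10", "E11", "E12", "E16", "E18", "E19"),
    "AM": ("E34", "E35", "E36", "E39", "E40", "E41", "E45", "E46"),
    "C": ("E7", "E31", "E55", "E80", "E106"),
    "UM": ("E102", "E103", "E104", "E108", "E109", "E110", "E115", "E116"),
    "P": ("E61", "E62", "E67", "E72", "E77", "E78"),
    "O": ("E70", "E71", "E74", "E75", "E76", "E81", "E82", "E83"),
}


class MontageError(ValueError):
    pass


@dataclass
class Montage:
    """Channel geometry plus ROI and hemisphere structure.

    Attributes
    ----------
    channels : list of str
        Ordered channel ids.
    coords : (n_channels, 3) ndarray
        Unit-norm positions, head frame (+x right, +y anterior, +z up).
    rois : dict
        ROI id -> tuple of channel ids.  ROI lists are not required to be
        disjoint; use :meth:`roi_overlap` to inspect.
    pairs : list of (str, str)
        Homologous (left, right) channel pairs, sorted by left id.
    midline : list of str
        Channels without a mirror partner (their own mirror image).
    """

    channels: list[str]
    coords: np.ndarray
    rois: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    midline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.channels), 3):
            raise MontageError("coords must be (n_channels, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise MontageError("non-finite coordinate")
        if len(set(self.channels)) != len(self.channels):
            dup = [c for c in self.channels if self.channels.count(c) > 1]
            raise MontageError(f"duplicate channel id: {sorted(set(dup))}")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(norms == 0):
            raise MontageError("zero-length coordinate")
        self.coords = self.coords / norms[:, None]
        for roi, chans in self.rois.items():
            if roi not in ROI_IDS:
                raise MontageError(f"unknown ROI id {roi!r}; expected one of {ROI_IDS}")
            missing = [c for c in chans if c not in self.channels]
            if missing:
                raise MontageError(f"ROI {roi} references unknown channels {missing}")
        self._index = {c: i for i, c in enumerate(self.channels)}

    # -- lookups ---------------------------------------------------------
    def index(self, channel: str) -> int:
        try:
            return self._index[channel]
        except KeyError:
            raise MontageError(f"unknown channel {channel!r}") from None

    def roi_indices(self, roi: str) -> np.ndarray:
        if roi not in self.rois:
            raise MontageError(f"ROI {roi!r} not defined in montage")
        return np.array([self.index(c) for c in self.rois[roi]])

    def roi_centroid(self, roi: str) -> np.ndarray:
        c = self.coords[self.roi_indices(roi)].mean(axis=0)
        return c / np.linalg.norm(c)

    def roi_overlap(self) -> dict[tuple[str, str], list[str]]:
        """Report channels shared between ROI pairs (verified, not assumed)."""
        out: dict[tuple[str, str], list[str]] = {}
        ids = sorted(self.rois)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                shared = sorted(set(self.rois[a]) & set(self.rois[b]))
                if shared:
                    out[(a, b)] = shared
        return out

    def flip_permutation(self) -> np.ndarray:
        """Index permutation swapping each pair's members; midline fixed.

        The permutation is an involution: applying it twice is the identity.
        """
        perm = np.arange(len(self.channels))
        for left, right in self.pairs:
            i, j = self.index(left), self.index(right)
            perm[i], perm[j] = j, i
        return perm

    def left_right_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (left, right) members of every pair, pair-aligned."""
        li = np.array([self.index(l) for l, _ in self.pairs], dtype=int)
        ri = np.array([self.index(r) for _, r in self.pairs], dtype=int)
        return li, ri


def homologous_pairs(
    channels: list[str], coords: np.ndarray, tol_deg: float = 3.0
) -> tuple[list[tuple[str, str]], list[str]]:
    """Match each left-hemisphere channel to its sagittal mirror image.

    A channel whose own mirror image lies within ``tol_deg`` great-circle
    degrees is midline.  A left channel (x < 0) is paired with the unique
    right channel within tolerance of its mirror image; two candidates
    within tolerance raise an error naming the channels.  Unmatched
    channels are reported as midline.

    Returns (pairs sorted by left id, midline ids in montage order).
    """
    if tol_deg <= 0:
        raise MontageError("tolerance must be positive")
    coords = np.asarray(coords, float)
    coords = coords / np.linalg.norm(coords, axis=1)[:, None]
    mirrored = coords * np.array([-1.0, 1.0, 1.0])
    cosang = np.clip(coords @ mirrored.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))  # ang[i, j]: channel i vs mirror of j

    n = len(channels)
    midline_mask = np.array([ang[i, i] < tol_deg for i in range(n)])
    pairs: list[tuple[str, str]] = []
    taken: set[int] = set()
    for i in range(n):
        if midline_mask[i] or coords[i, 0] >= 0:
            continue  # only walk left-hemisphere channels
        cand = [
            j
            for j in range(n)
            if j != i and not midline_mask[j] and coords[j, 0] > 0 and ang[j, i] < tol_deg
        ]
        if len(cand) > 1:
            names = [channels[j] for j in cand]
            raise MontageError(
                f"ambiguous mirror match for {channels[i]}: candidates {names}"
            )
        if cand:
            j = cand[0]
            if j in taken:
                raise MontageError(
                    f"right channel {channels[j]} matched by two left channels"
                )
            taken.add(j)
            pairs.append((channels[i], channels[j]))
    paired = {c for p in pairs for c in p}
    midline = [c for c in channels if c not in paired]
    pairs.sort(key=lambda p: p[0])
    return pairs, midline


def load_montage(source: str | Path | dict, tol_deg: float = 3.0) -> Montage:
    """Load a montage from a JSON document (path or parsed dict).

    Expected keys: ``channels`` (list of {channel, x, y, z}), optional
    ``rois`` (roi -> channel list) and optional ``pairs``.  When pairs are
    absent they are derived geometrically by sagittal mirror matching.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    rows = doc["channels"]
    channels = [r["channel"] for r in rows]
    coords = np.array([[r["x"], r["y"], r["z"]] for r in rows], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise MontageError("non-finite coordinate in montage document")
    rois = {k: tuple(v) for k, v in doc.get("rois", {}).items()}
    if "pairs" in doc:
        pairs = [tuple(p) for p in doc["pairs"]]
        paired = {c for p in pairs for c in p}
        midline = [c for c in channels if c not in paired]
    else:
        pairs, midline = homologous_pairs(channels, coords, tol_deg)
    return Montage(channels, coords, rois, pairs, midline)


def save_montage(montage: Montage, path: str | Path) -> None:
    doc = {
        "channels": [
            {"channel": c, "x": x, "y": y, "z": z}
            for c, (x, y, z) in zip(montage.channels, montage.coords)
        ],
        "rois": {k: list(v) for k, v in montage.rois.items()},
        "pairs": [list(p) for p in montage.pairs],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def geodesic_montage(tol_deg: float = 3.0) -> Montage:
    """The packaged 129-channel geodesic montage (E1..E128 + Cz).

    Positions come from the standard GSN-HydroCel-129 layout shipped with
    MNE-Python; they are centered by a least-squares sphere fit and
    normalized to the unit sphere.  Homologous pairs are derived
    geometrically; the idealized layout yields 59 pairs and 11 midline
    channels.
    """
    import mne

    mont = mne.channels.make_standard_montage("GSN-HydroCel-129")
    pos = mont.get_positions()["ch_pos"]
    channels = list(pos)
    P = np.array([pos[c] for c in channels], dtype=float)
    # least-squares sphere fit: ||p - c||^2 = r^2
    A = np.c_[2 * P, np.ones(len(P))]
    sol, *_ = np.linalg.lstsq(A, (P**2).sum(axis=1), rcond=None)
    coords = P - sol[:3]
    pairs, midline = homologous_pairs(channels, coords, tol_deg)
    return Montage(channels, coords, dict(GEODESIC_ROIS), pairs, midline)


def roi_signal(data: np.ndarray, channels: list[str], montage: Montage, roi: str) -> np.ndarray:
    """Sample-wise arithmetic mean of the ROI's channels.

    ``data`` is (n_channels, n_samples) ordered as ``channels``.
    """
    index = {c: i for i, c in enumerate(channels)}
    missing = [c for c in montage.rois[roi] if c not in index]
    if missing:
        raise MontageError(f"ROI {roi} channels missing from data: {missing}")
    rows = [index[c] for c in montage.rois[roi]]
    return np.asarray(data, float)[rows].mean(axis=0)
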