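"""Synthetic resting-state EEG cohorts with planted group effects.

The generator replaces unavailable clinical recordings with 90-s
multichannel surrogates that carry the statistical structure the analysis
assumes:

* per-channel 1/f^gamma Gaussian background, synthesized in the frequency
  domain;
* band-limited oscillator sources placed at ROI centroids and spread to
  the electrodes by an exponential distance-decay kernel on the unit
  sphere (a stand-in for volume conduction that gives the surface
  Laplacian something real to sharpen);
* an alpha oscillator whose spectral peak sits at the subject's drawn
  peak-alpha frequency;
* pairwise shared-source fractions that plant ROI-pair coherence, solved
  per subject from the exact expected cross-spectra of the analysis path
  (Laplacian transform -> ROI average -> Welch coherence);
* per-band hemispheric power ratios that plant the directional brain
  symmetry index.

All per-subject parameters (band power in dB, peak-alpha frequency,
dirBSI, coherence) are drawn from group-level normal distributions whose
default means and SDs are the study-condition targets; the synthesis then
realizes those draws in expectation through an analytic calibration: the
mixing, referencing, ROI averaging and Laplacian are all linear maps with
known second-order statistics, so expected band powers and coherences can
be computed exactly and source variances / shared fractions solved for.

Subjects are generated in a canonical "lesion-right" space; left-lesion
patients are returned with channels mirrored so that the preprocessing
flip restores the canonical space.  All randomness flows from one root
seed through per-subject spawned generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, nnls

from . import csd as _csd
from .montage import Montage, geodesic_montage
from .preprocess import Recording
from .spectral import BAND_ORDER, BANDS

GROUPS = ("HC", "P1", "P2", "P3")


class EffectError(ValueError):
    pass


@dataclass
class EffectSpec:
    """Planted group-level feature targets; values are (mean, sd) tuples."""

    group: str
    paf_mean_hz: float = 10.0
    paf_sd_hz: float = 1.0
    #: (roi, band) -> (mean dB, sd dB); absent entries plant no oscillator.
    roi_band_power_db: dict = field(default_factory=dict)
    #: band name -> (mean, sd) of the planted dirBSI.
    dirbsi: dict = field(default_factory=dict)
    #: (roi_a, roi_b, band) -> (mean, sd) of the planted coherence.
    coherence: dict = field(default_factory=dict)
    #: behavioral scale -> (mean, sd, lo, hi); drawn coupled to the
    #: subject's planted alpha-power deviation so EEG-behavior
    #: correlations are non-null.
    behavior: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 7.0 <= self.paf_mean_hz <= 12.0:
            raise EffectError("peak-alpha mean must lie inside the alpha band [7, 12]")
        for key, (m, _sd) in self.coherence.items():
            if not 0.0 <= m < 0.95:
                raise EffectError(
                    f"coherence target {m} for {key} unreachable with nonzero noise"
                )
        for band, (m, _sd) in self.dirbsi.items():
            if not -1.0 < m < 1.0:
                raise EffectError(f"dirBSI target {m} for {band} outside (-1, 1)")


@dataclass
class CohortConfig:
    group_sizes: dict = field(
        default_factory=lambda: {"HC": 22, "P1": 22, "P2": 18, "P3": 17}
    )
    fs: float = 250.0
    duration_s: float = 120.0  # recorded; 90 clean seconds are extracted
    seed: int = 0
    lesion_side_mix: float = 0.5      # fraction of left-lesion patients
    mixing_decay_rad: float = 0.35    # volume-conduction kernel decay length
    noise_gamma: float = 1.0          # 1/f exponent of the background
    noise_amp: float = 6e-4           # background PSD at 1 Hz, uV^2/Hz

    def __post_init__(self):
        if self.fs < 250:
            raise EffectError("sampling rate must be >= 250 Hz")
        if self.duration_s < 90:
            raise EffectError("duration must be >= 90 s for the default pipeline")
        for g, n in self.group_sizes.items():
            if n != 0 and n < 2:
                raise EffectError(f"group {g} size must be 0 or >= 2")


def default_effects() -> dict[str, EffectSpec]:
    """Study-condition effect targets for the four groups.

    Means and SDs of the printed group summaries serve as the planted
    feature distributions: patients show elevated alpha power (largest at
    the ipsilesional motor region), slowed peak-alpha frequency, a
    positive theta dirBSI (ipsilesional dominance), stronger theta
    fronto-motor coherence and weaker alpha/beta1 parieto-occipital
    coherence; the brainstem subgroup has higher parietal beta1 power and
    a symmetric alpha dirBSI, unlike the two other subgroups.  Values not
    printed for a given cell are filled with typical resting-EEG levels.
    """
    hc_power = {}
    p_power = {}
    for roi in ("F", "AM", "C", "UM", "P", "O"):
        hc_power[(roi, "theta")] = (-17.0, 6.0)
        p_power[(roi, "theta")] = (-13.0, 6.5)
    hc_alpha = {"F": -16.0, "AM": -14.89, "UM": -14.89, "C": -15.5, "P": -13.5, "O": -12.0}
    p_alpha = {"F": -15.0, "AM": -4.36, "UM": -4.36, "C": -5.5, "P": -3.5, "O": -2.5}
    for roi, v in hc_alpha.items():
        hc_power[(roi, "alpha")] = (v, 7.88 if roi in ("AM", "UM") else 7.5)
    for roi, v in p_alpha.items():
        p_power[(roi, "alpha")] = (v, 9.10 if roi in ("AM", "UM") else 9.0)
    for roi in ("F", "AM", "C", "UM", "P", "O"):
        hc_power[(roi, "beta1")] = (-19.0, 5.0)
        p_power[(roi, "beta1")] = (-19.0, 5.0) if roi in ("AM", "UM") else (-17.0, 5.0)
    # parietal beta1 separates the lesion subgroups
    beta1_P = {"P1": (-17.27, 4.90), "P2": (-19.01, 4.63), "P3": (-13.71, 4.75)}

    hc = EffectSpec(
        group="HC", paf_mean_hz=9.93, paf_sd_hz=1.09,
        roi_band_power_db=hc_power,
        dirbsi={"theta": (-0.026, 0.101), "alpha": (0.0, 0.09), "beta1": (0.0, 0.09)},
        coherence={
            ("F", "AM", "theta"): (0.100, 0.074),
            ("F", "UM", "theta"): (0.117, 0.071),
            ("P", "O", "alpha"): (0.274, 0.120),
            ("P", "O", "beta1"): (0.225, 0.113),
        },
    )
    alpha_bsi = {"P1": (0.068, 0.087), "P2": (0.063, 0.103), "P3": (-0.021, 0.090)}
    um_p_theta = {"P1": (0.108, 0.066), "P2": (0.169, 0.109), "P3": (0.114, 0.112)}
    am_um_theta = {"P1": (0.120, 0.110), "P2": (0.150, 0.123), "P3": (0.086, 0.105)}
    behavior = {
        "P1": {"MMT": (2.1, 1.2, 0, 5), "FMA": (16.7, 5.0, 0, 66),
               "MMSE": (26.0, 3.0, 0, 30), "ADL": (45.7, 14.7, 0, 100)},
        "P2": {"MMT": (3.3, 0.7, 0, 5), "FMA": (22.2, 5.4, 0, 66),
               "MMSE": (17.0, 5.0, 0, 30), "ADL": (60.0, 25.3, 0, 100)},
        "P3": {"MMT": (3.2, 0.9, 0, 5), "FMA": (25.4, 4.8, 0, 66),
               "MMSE": (24.0, 4.0, 0, 30), "ADL": (59.7, 22.9, 0, 100)},
    }
    out = {"HC": hc}
    for g in ("P1", "P2", "P3"):
        power = dict(p_power)
        power[("P", "beta1")] = beta1_P[g]
        out[g] = EffectSpec(
            group=g, paf_mean_hz=8.75, paf_sd_hz=1.02,
            roi_band_power_db=power,
            dirbsi={"theta": (0.061, 0.122), "alpha": alpha_bsi[g], "beta1": (0.0, 0.1)},
            coherence={
                ("F", "AM", "theta"): (0.136, 0.102),
                ("F", "UM", "theta"): (0.162, 0.115),
                ("UM", "P", "theta"): um_p_theta[g],
                ("AM", "UM", "theta"): am_um_theta[g],
                ("P", "O", "alpha"): (0.222, 0.088),
                ("P", "O", "beta1"): (0.187, 0.088),
            },
            behavior=behavior[g],
        )
    return out


# -- geometry cache ------------------------------------------------------

class _Geometry:
    """Linear-algebra precomputations for one montage/config combination."""

    def __init__(self, montage: Montage, decay: float, csd_lambda: float = 1e-5):
        self.montage = montage
        d = len(montage.channels)
        coords = montage.coords
        rois = [r for r in ("F", "AM", "C", "UM", "P", "O") if r in montage.rois]
        self.rois = rois
        cent = np.array([montage.roi_centroid(r) for r in rois])
        ang = np.arccos(np.clip(coords @ cent.T, -1, 1))   # (d, n_roi)
        self.K = np.exp(-ang / decay)
        rave = np.zeros((len(rois), d))
        for i, r in enumerate(rois):
            idx = montage.roi_indices(r)
            rave[i, idx] = 1.0 / len(idx)
        self.rave = rave
        self.U = rave @ (self.K - self.K.mean(axis=0, keepdims=True))  # CAR'd gains
        ra = rave - rave.mean(axis=1, keepdims=True)
        self.vnorm2 = np.sum(ra**2, axis=1)                 # CAR'd noise gain
        splines = _csd.build_spline_matrices(montage)
        self.Lc = rave @ _csd.csd_transform(splines, csd_lambda)
        self.Gc = self.Lc @ self.K
        self.Ncsd = self.Lc @ self.Lc.T
        li, ri = montage.left_right_indices()
        self.left_idx, self.right_idx = li, ri
        self.flip_perm = montage.flip_permutation()


_GEOM_CACHE: dict[tuple, _Geometry] = {}


def _geometry(montage: Montage, decay: float) -> _Geometry:
    key = (id(montage), decay)
    if key not in _GEOM_CACHE:
        _GEOM_CACHE[key] = _Geometry(montage, decay)
    return _GEOM_CACHE[key]


# -- subject parameter draws --------------------------------------------

#: Loading of a subject's global power deviation shared by every (ROI,
#: band) cell.  Most between-subject power variance is a whole-head gain
#: (skull conductivity, overall rhythm amplitude), so cell deviations
#: within a subject are strongly shared; this keeps within-subject
#: ROI-to-ROI and band-to-band spreads physiological (a few dB, no
#: spectral cliffs at band edges) while preserving the marginal
#: N(mean, sd) of every cell.
POWER_SHARED_RHO = 0.95


def draw_subject_params(effect: EffectSpec, rng: np.random.Generator) -> dict:
    """One subject's planted feature values, drawn from the group targets."""
    params: dict = {"group": effect.group}
    params["paf_hz"] = float(
        np.clip(rng.normal(effect.paf_mean_hz, effect.paf_sd_hz), 7.5, 11.5)
    )
    # hierarchical dB draws: subject-global deviation + small cell residual;
    # the homologous motor ROIs share one residual per band so the
    # hemispheric power base stays symmetric and the planted dirBSI gain
    # is not confounded
    # deviations are truncated (global +-2 sd, residual +-2.5 sd): real
    # band powers are bounded, and an untruncated +3 sd whole-head draw
    # would exceed the +-100 uV screening threshold on every window -- a
    # recording no cohort would contain
    power: dict = {}
    z_subject = float(np.clip(rng.normal(), -2.0, 2.0))
    r_resid = np.sqrt(1.0 - POWER_SHARED_RHO**2)
    resid: dict = {}
    for roi, band in sorted(effect.roi_band_power_db):
        key = ("motor" if roi in ("AM", "UM") else roi, band)
        if key not in resid:
            resid[key] = float(np.clip(rng.normal(), -2.5, 2.5))
        m, sd = effect.roi_band_power_db[(roi, band)]
        z = POWER_SHARED_RHO * z_subject + r_resid * resid[key]
        power[(roi, band)] = float(m + sd * z)
    params["power_db"] = power
    params["dirbsi"] = {
        band: float(np.clip(rng.normal(m, sd), -0.6, 0.6))
        for band, (m, sd) in effect.dirbsi.items()
    }
    params["coherence"] = {
        key: float(np.clip(rng.normal(m, sd), 0.005, 0.85))
        for key, (m, sd) in effect.coherence.items()
    }
    behavior = {}
    if effect.behavior:
        # couple scores to the subject's alpha-power deviation at AM so the
        # Spearman stage has signal to find
        key = ("AM", "alpha")
        if key in effect.roi_band_power_db and key in params["power_db"]:
            m, sd = effect.roi_band_power_db[key]
            z = 0.0 if sd == 0 else (params["power_db"][key] - m) / sd
        else:
            z = 0.0
        for scale, (m, sd, lo, hi) in effect.behavior.items():
            val = m + sd * (-0.5 * z + np.sqrt(0.75) * rng.normal())
            behavior[scale] = float(np.clip(val, lo, hi))
    params["behavior"] = behavior
    return params


# -- calibration ---------------------------------------------------------

def _band_env(freqs: np.ndarray, band_name: str, paf_hz: float,
              inset_hz: float = 0.25, ramp_hz: float = 0.5) -> np.ndarray:
    """Spectral envelope of a band source, normalized to unit band power.

    The broadband part is cosine-tapered and inset from the band edges so
    that the 2-s Welch window's smearing does not spill a spectral cliff
    into the neighbouring band (which would corrupt peak-alpha detection
    at the shared 7-Hz edge).  The alpha envelope adds a Gaussian peak at
    the subject's peak-alpha frequency on top of the tapered floor.
    """
    band = BANDS[band_name]
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    lo, hi = band.lo + inset_hz, band.hi - inset_hz
    base = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    base[inside] = 1.0
    up = inside & (freqs < lo + ramp_hz)
    base[up] = 0.5 - 0.5 * np.cos(np.pi * (freqs[up] - lo) / ramp_hz)
    down = inside & (freqs > hi - ramp_hz)
    base[down] = 0.5 - 0.5 * np.cos(np.pi * (hi - freqs[down]) / ramp_hz)
    if base.sum() == 0:
        base[:] = 1.0
    if band_name == "alpha":
        peak = np.exp(-0.5 * ((freqs - paf_hz) / 0.5) ** 2)
        env = 0.4 * base / base.sum() + 0.6 * peak / max(peak.sum(), 1e-300)
    else:
        env = base / base.sum()
    return env / df  # density: sum(env * df) == 1


def _solve_source_variances(geom: _Geometry, band_name: str,
                            power_db: dict, p_bg: float,
                            strict: bool = False) -> np.ndarray:
    """Source band variances meeting the ROI band-power targets in expectation.

    Solved by nonnegative least squares on the squared CAR'd mixing gains:
    a target that falls below the leakage floor of its neighbours (possible
    in the tails of the dB draws, which span orders of magnitude on the
    linear scale) clamps that source to zero and the ROI sits at the floor
    rather than failing.  Targets below the *background* floor are a hard
    error -- no source variance can reach them.
    """
    rois = geom.rois
    active = [i for i, r in enumerate(rois) if (r, band_name) in power_db]
    S = np.zeros(len(rois))
    if not active:
        return S
    targets = np.array([10 ** (power_db[(rois[i], band_name)] / 10) for i in active])
    rhs = targets - geom.vnorm2[active] * p_bg
    if np.any(rhs <= 0):
        if strict:
            bad = [rois[i] for i, v in zip(active, rhs) if v <= 0]
            raise EffectError(
                f"{band_name} power target below the background floor for ROI(s) {bad}"
            )
        # a tail draw below the background floor clamps to the floor
        rhs = np.maximum(rhs, 1e-12 * max(targets.max(), 1e-30))
    M = (geom.U[np.ix_(active, active)]) ** 2
    # scale rows so every target carries equal relative weight in the fit
    w = 1.0 / rhs
    sol, _ = nnls(M * w[:, None], rhs * w)
    S[active] = sol
    return S


def _expected_msc(geom, psi, env, beta, X, Y):
    P = geom.Gc @ psi @ geom.Gc.T
    ax = P[X, X] * env + geom.Ncsd[X, X] * beta
    ay = P[Y, Y] * env + geom.Ncsd[Y, Y] * beta
    cr = P[X, Y] * env + geom.Ncsd[X, Y] * beta
    return float(np.mean(cr**2 / (ax * ay)))


def _solve_source_covariance(geom: _Geometry, band_name: str, S: np.ndarray,
                             env: np.ndarray, beta: np.ndarray,
                             coh_targets: dict, strict: bool = False) -> np.ndarray:
    """Source band-covariance matrix Psi hitting the coherence targets.

    Off-diagonal entries for targeted ROI pairs are solved (scalar root
    finds, two sweeps) from the exact expected band-mean coherence of the
    analysis path (Laplacian -> ROI average -> Welch), including source
    leakage through the mixing kernel and the background floor.  A
    baseline coherence already at or above a target clamps the entry to
    zero (best effort).  The resulting matrix must be positive
    semidefinite -- i.e. the joint correlation structure must be
    physically realizable -- otherwise the targets are unreachable.
    """
    rois = geom.rois
    psi = np.diag(S)
    # the Welch magnitude-squared-coherence estimator is biased upward by
    # about (1 - C)^2 / K_eff (K_eff ~ 60 effective windows for 2-s Hamming
    # windows with 50% overlap over 90 s); the solver aims the *estimator*
    # at the target, so the true coherence target is lowered accordingly
    k_eff = 60.0
    pairs = []
    for (a, b, bn), c in coh_targets.items():
        if bn != band_name:
            continue
        if a not in rois or b not in rois:
            raise EffectError(f"coherence target references unknown ROI in {(a, b, bn)}")
        X, Y = rois.index(a), rois.index(b)
        if S[X] <= 0 or S[Y] <= 0:
            # a clamped (leakage-floored) source cannot carry a shared
            # component; the pair's coherence stays at the baseline
            continue
        c = max(c - (1.0 - c) ** 2 / k_eff, 0.5 * c)
        pairs.append((X, Y, c))
    if not pairs:
        return psi
    for _sweep in range(2):
        for X, Y, c in pairs:
            cap = 0.97 * np.sqrt(S[X] * S[Y])

            def f(v):
                psi[X, Y] = psi[Y, X] = v
                return _expected_msc(geom, psi, env, beta, X, Y) - c

            if f(0.0) >= 0:
                v = 0.0  # baseline (leakage + noise) already at/above target
            elif f(cap) <= 0:
                v = cap
            else:
                v = brentq(f, 0.0, cap, xtol=1e-12)
            psi[X, Y] = psi[Y, X] = v
    active = np.where(S > 0)[0]
    if len(active):
        block = psi[np.ix_(active, active)]
        eigmin = np.linalg.eigvalsh(block)[0]
        if strict and eigmin < -0.05 * S.max():
            raise EffectError(
                f"joint {band_name} coherence targets are not realizable "
                "(source covariance far from positive semidefinite)"
            )
        if eigmin < 0:
            # tail draws can make the joint correlation infeasible; project
            # to the PSD cone and restore the planted variances on the
            # diagonal (best effort for that subject)
            w, v = np.linalg.eigh(block)
            block = (v * np.clip(w, 0.0, None)) @ v.T
            scale = np.sqrt(S[active] / np.clip(np.diag(block), 1e-300, None))
            block = block * np.outer(scale, scale)
            psi[np.ix_(active, active)] = block
    return psi


def _solve_hemisphere_gain(geom: _Geometry, cov_band: np.ndarray, target: float,
                           u_max: float = 4.0) -> float:
    """Right-hemisphere amplitude gain u (left gets 1/u) whose *measured*
    dirBSI -- per-channel band power after common-average referencing,
    summed over homologous pairs -- equals the target."""
    ri, li = geom.right_idx, geom.left_idx

    def measured(u):
        g = np.ones(len(cov_band))
        g[ri] = u
        g[li] = 1.0 / u
        M = cov_band * np.outer(g, g)
        # diag of (I - 11'/d) M (I - 11'/d)
        rm = M.mean(axis=1)
        diag = np.diag(M) - 2 * rm + M.mean()
        R, L = diag[ri].sum(), diag[li].sum()
        return (R - L) / (R + L)

    f = lambda u: measured(u) - target
    lo, hi = 1.0 / u_max, u_max
    if f(lo) >= 0:
        return lo
    if f(hi) <= 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-10))


# -- synthesis -----------------------------------------------------------

def _cnormal(rng: np.random.Generator, *shape) -> np.ndarray:
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)


def generate_subject(
    config: CohortConfig,
    effect: EffectSpec,
    subject_seed,
    montage: Montage | None = None,
    lesion_side: str = "none",
) -> Recording:
    """Synthesize one subject's recording (deterministic for a fixed seed)."""
    montage = montage or geodesic_montage()
    geom = _geometry(montage, config.mixing_decay_rad)
    rng = np.random.default_rng(subject_seed)
    params = draw_subject_params(effect, rng)

    n = int(round(config.duration_s * config.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    df = config.fs / n
    d = len(montage.channels)
    X = np.zeros((d, len(freqs)), dtype=complex)

    # 1/f^gamma background, synthesized up to 45 Hz (the analysis band-pass
    # removes everything above 30 Hz anyway)
    f_hi = min(45.0, config.fs / 2 - 1.0)
    bg_mask = (freqs >= 0.5) & (freqs <= f_hi)
    beta_full = np.zeros_like(freqs)
    if config.noise_amp > 0:
        beta_full[bg_mask] = config.noise_amp / freqs[bg_mask] ** config.noise_gamma
        X[:, bg_mask] = n * np.sqrt(beta_full[bg_mask] * df / 2) * _cnormal(
            rng, d, int(bg_mask.sum())
        )

    for band_name in BAND_ORDER:
        band = BANDS[band_name]
        mask = (freqs >= band.lo) & (freqs < band.hi)
        fb = freqs[mask]
        env = _band_env(fb, band_name, params["paf_hz"])
        p_bg = float(np.sum(beta_full[mask]) * df)
        # configured mean targets must be reachable (hard error if not);
        # individual tail draws clamp / project instead.  Validation runs
        # once per effect/band and is cached on the geometry object.
        vkey = (id(effect), band_name, round(params["paf_hz"], 1))
        if not hasattr(geom, "_validated"):
            geom._validated = set()
        if vkey not in geom._validated:
            mean_targets = {k: m for k, (m, _sd) in effect.roi_band_power_db.items()}
            S_mean = _solve_source_variances(geom, band_name, mean_targets, p_bg,
                                             strict=True)
            mean_coh = {k: m for k, (m, _sd) in effect.coherence.items()}
            _solve_source_covariance(geom, band_name, S_mean, env,
                                     beta_full[mask], mean_coh, strict=True)
            geom._validated.add(vkey)
        S = _solve_source_variances(geom, band_name, params["power_db"], p_bg)
        psi = _solve_source_covariance(
            geom, band_name, S, env, beta_full[mask], params["coherence"]
        )
        active = np.where(S > 0)[0]
        if len(active):
            # matrix square root of the source covariance (robust to a
            # semidefinite boundary, unlike Cholesky)
            w, v = np.linalg.eigh(psi[np.ix_(active, active)])
            A = v * np.sqrt(np.clip(w, 0.0, None))
            cfac = n * np.sqrt(env * df / 2)
            z = _cnormal(rng, len(active), len(fb))
            X[:, mask] += geom.K[:, active] @ (A @ z) * cfac

        # hemispheric amplitude gains planting the band dirBSI (canonical
        # space: positive = right/ipsilesional predominance).  The common
        # average computed downstream subtracts a symmetric component and
        # dilutes a naive power-ratio gain, so the gain is solved against
        # the post-CAR expected channel powers.
        B = params["dirbsi"].get(band_name, 0.0)
        if B:
            cov_band = geom.K[:, active] @ psi[np.ix_(active, active)] \
                @ geom.K[:, active].T + p_bg * np.eye(len(geom.K))
            if np.trace(cov_band) <= 0:
                continue
            u = _solve_hemisphere_gain(geom, cov_band, B)
            X[np.ix_(geom.right_idx, np.where(mask)[0])] *= u
            X[np.ix_(geom.left_idx, np.where(mask)[0])] *= 1.0 / u

    data = np.fft.irfft(X, n=n)
    if lesion_side == "left":
        data = data[geom.flip_perm]  # pipeline flip will restore canonical space
    meta = {
        "group": effect.group,
        "lesion_side": lesion_side,
        "planted": params,
    }
    return Recording(data, config.fs, list(montage.channels), meta)


def generate_cohort(
    config: CohortConfig,
    effects: dict[str, EffectSpec] | None = None,
    montage: Montage | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Full cohort plus manifest (subject_id, group, lesion side, scores)."""
    effects = effects or default_effects()
    montage = montage or geodesic_montage()
    for g, size in config.group_sizes.items():
        if size > 0 and g not in effects:
            raise EffectError(f"no EffectSpec for group {g}")
    root = np.random.SeedSequence(config.seed)
    total = sum(config.group_sizes.values())
    child_seeds = root.spawn(total + 1)
    side_rng = np.random.default_rng(child_seeds[-1])

    recordings, rows = [], []
    k = 0
    for g in GROUPS:
        size = config.group_sizes.get(g, 0)
        if size == 0:
            continue
        if g == "HC":
            sides = ["none"] * size
        else:
            n_left = int(round(config.lesion_side_mix * size))
            sides = ["left"] * n_left + ["right"] * (size - n_left)
            side_rng.shuffle(sides)
        for j in range(size):
            sid = f"{g}-{j + 1:02d}"
            rec = generate_subject(config, effects[g], child_seeds[k], montage, sides[j])
            rec.meta["subject_id"] = sid
            recordings.append(rec)
            row = {"subject_id": sid, "group": g, "lesion_side": sides[j]}
            for scale in ("MMT", "FMA", "MMSE", "ADL"):
                row[scale] = rec.meta["planted"]["behavior"].get(scale, np.nan)
            rows.append(row)
            k += 1
    return recordings, pd.DataFrame(rows)


def inject_artifacts(
    rec: Recording, amplitude_uv: float, times_s, width_s: float = 0.05
) -> Recording:
    """Add Gaussian-shaped transients of the given peak amplitude."""
    data = rec.data.copy()
    t = np.arange(data.shape[1]) / rec.fs
    for t0 in np.atleast_1d(times_s):
        if not 0 <= t0 <= rec.duration_s:
            raise EffectError(f"spike time {t0} outside recording")
        data += amplitude_uv * np.exp(-0.5 * ((t - t0) / width_s) ** 2)
    return Recording(data, rec.fs, list(rec.channels), dict(rec.meta))


def sample_features(
    group_sizes: dict[str, int],
    effects: dict[str, EffectSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-level cohort draws (no signal synthesis).

    One row per subject with the planted per-subject feature values --
    exactly the distributions the EEG synthesis realizes in expectation.
    Used for statistical power and null-calibration studies where the
    signal path adds nothing but runtime.
    """
    effects = effects or default_effects()
    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        size = group_sizes.get(g, 0)
        for j in range(size):
            p = draw_subject_params(effects[g], rng)
            row = {"subject_id": f"{g}-{j + 1:02d}", "group": g}
            for (roi, band), v in p["power_db"].items():
                row[f"psd:{roi}:{band}"] = v
            row["paf:AM"] = p["paf_hz"]
            for band, v in p["dirbsi"].items():
                row[f"dirbsi:{band}"] = v
            for (a, b, band), v in p["coherence"].items():
                row[f"fc:{a}-{b}:{band}"] = v
            for scale, v in p["behavior"].items():
                row[scale] = v
            rows.append(row)
    return pd.DataFrame(rows)
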