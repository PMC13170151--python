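"""CSP + LDA decoding with leave-one-subject-out cross-validation.

Each subject contributes one trace-normalized covariance matrix per band
(theta, alpha, beta1) from the band-filtered 90-s segment -- the subject is
the trial, so every cross-validation fold yields exactly one decision per
held-out subject.  Common spatial patterns solve the generalized
eigenproblem

    Sigma_A w = lambda (Sigma_A + Sigma_B) w,

keeping the eigenvectors at the largest and smallest eigenvalues; the
log-variance of the projections (log w' Sigma w) forms the feature vector
(3 bands x 2 filters = 6 per binary model).  Class-mean covariances are
shrunk toward the scaled identity with a Ledoit-Wolf-style intensity
estimated from the between-subject dispersion, since channel count far
exceeds subjects per class.  Three-class decoding concatenates the
one-vs-one CSP features (18) into a single multiclass LDA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve

from .spectral import BAND_ORDER, BANDS, BandDef


class DecodingError(ValueError):
    pass


# -- per-subject covariances --------------------------------------------

def subject_covariances(
    data: np.ndarray,
    fs: float,
    bands: dict[str, BandDef] | None = None,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """Band-filtered (zero-phase), trace-normalized sample covariances."""
    bands = bands or BANDS
    data = np.asarray(data, float)
    if data.shape[0] < 2:
        raise DecodingError("need at least 2 channels")
    if data.shape[1] < 10 * fs:
        raise DecodingError("segment shorter than 10 s")
    out = {}
    for name, band in bands.items():
        sos = signal.butter(order, (band.lo, band.hi), btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, data, axis=-1)
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / (x.shape[1] - 1)
        tr = np.trace(cov)
        if tr <= 0:
            raise DecodingError(f"rank-0 input in band {name}")
        out[name] = cov / tr
    return out


def is_rank_deficient(cov: np.ndarray, tol: float = 1e-10) -> bool:
    return bool(np.linalg.eigvalsh(cov)[0] < tol * np.trace(cov))


# -- CSP -----------------------------------------------------------------

@dataclass
class CspModel:
    filters: np.ndarray     # (n_channels, n_filters), [largest, ..., smallest]
    patterns: np.ndarray    # (n_channels, n_filters)
    eigenvalues: np.ndarray
    classes: tuple = ()
    band: str = ""


def shrink_mean_covariance(covs: list[np.ndarray]) -> np.ndarray:
    """Mean covariance shrunk toward (tr/d) I with a data-driven intensity.

    Intensity follows the Ledoit-Wolf construction with subjects as
    observations: b2 = mean squared Frobenius dispersion of the subject
    matrices around the mean (scaled by 1/n), d2 = squared distance of the
    mean from its isotropic target, shrinkage = min(b2/d2, 1).
    """
    covs = [np.asarray(c, float) for c in covs]
    S = np.mean(covs, axis=0)
    d = S.shape[0]
    mu = np.trace(S) / d
    target = mu * np.eye(d)
    d2 = float(np.sum((S - target) ** 2))
    n = len(covs)
    b2 = float(np.mean([np.sum((c - S) ** 2) for c in covs])) / n
    alpha = 0.0 if d2 == 0 else min(b2 / d2, 1.0)
    return (1 - alpha) * S + alpha * target


def solve_csp(sigma_a: np.ndarray, sigma_b: np.ndarray, n_filters: int = 2) -> CspModel:
    """Generalized eigenproblem Sigma_A w = lambda (Sigma_A + Sigma_B) w.

    Eigenvalues lie in [0, 1] and swap to 1 - lambda when classes swap.
    Kept filters bracket the spectrum: the top ``n_filters // 2`` at the
    largest eigenvalues and the bottom at the smallest.  Patterns are the
    corresponding columns of the inverse-transpose of the full eigenvector
    basis.
    """
    if n_filters % 2 or n_filters < 2:
        raise DecodingError("n_filters must be a positive even number")
    comp = sigma_a + sigma_b
    try:
        w, v = linalg.eigh(sigma_a, comp)
    except linalg.LinAlgError as err:
        raise DecodingError(f"ill-conditioned composite covariance: {err}") from err
    order = np.argsort(w)[::-1]  # descending: largest eigenvalue first
    w, v = w[order], v[:, order]
    half = n_filters // 2
    keep = list(range(half)) + list(range(len(w) - half, len(w)))
    try:
        patterns_full = np.linalg.pinv(v.T)
    except np.linalg.LinAlgError as err:
        raise DecodingError(f"singular filter basis: {err}") from err
    return CspModel(
        filters=v[:, keep], patterns=patterns_full[:, keep], eigenvalues=w[keep]
    )


def fit_csp(
    covs_a: list[np.ndarray], covs_b: list[np.ndarray],
    n_filters: int = 2, shrinkage: str | float = "lw",
) -> CspModel:
    """CSP from per-subject covariance lists of two classes.

    The eigenproblem is restricted to the principal subspace of the raw
    (unshrunk) composite covariance: directions the data never occupy --
    e.g. the all-ones direction nulled by common-average referencing --
    would otherwise surface as spurious discriminative filters whose
    projected variance is numerically zero for every subject.
    """
    if len(covs_a) < 2 or len(covs_b) < 2:
        raise DecodingError("need at least 2 subjects per class")
    raw_comp = np.mean(covs_a, axis=0) + np.mean(covs_b, axis=0)
    w, u = np.linalg.eigh(raw_comp)
    keep = w > 1e-10 * w.max()
    basis = u[:, keep]  # (d, k) principal subspace of the data
    if shrinkage == "lw":
        sa, sb = shrink_mean_covariance(covs_a), shrink_mean_covariance(covs_b)
    else:
        lam = float(shrinkage)
        def _shr(covs):
            S = np.mean(covs, axis=0)
            mu = np.trace(S) / S.shape[0]
            return (1 - lam) * S + lam * mu * np.eye(S.shape[0])
        sa, sb = _shr(covs_a), _shr(covs_b)
    model = solve_csp(basis.T @ sa @ basis, basis.T @ sb @ basis,
                      n_filters=n_filters)
    # map subspace filters/patterns back to channel space
    return CspModel(filters=basis @ model.filters,
                    patterns=basis @ model.patterns,
                    eigenvalues=model.eigenvalues)


def csp_features(cov_by_band: dict[str, np.ndarray], models: dict[str, CspModel]) -> np.ndarray:
    """Log-variance of each filter projection, concatenated across bands."""
    feats = []
    for band in BAND_ORDER:
        if band not in models:
            continue
        W = models[band].filters
        var = np.einsum("cf,cd,df->f", W, cov_by_band[band], W)
        if np.any(var <= 0):
            raise DecodingError(f"non-positive projected variance in band {band}")
        feats.append(np.log(var))
    return np.concatenate(feats)


# -- evaluation ----------------------------------------------------------

def roc_auc(scores, labels, positive) -> tuple[float, pd.DataFrame]:
    """Mann-Whitney concordance AUC (tie-corrected) plus ROC points."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    y = (labels == positive).astype(int)
    if y.min() == y.max():
        raise DecodingError("ROC needs both classes present")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class DecodingResult:
    subjects: list
    labels: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray           # binary: signed distance; 3-class: max posterior
    accuracy: float
    auc: float | None
    roc_points: pd.DataFrame | None
    confusion: pd.DataFrame
    confusion_normalized: pd.DataFrame
    classes: tuple
    fold_train_subjects: list = field(default_factory=list)

    def audit_no_leakage(self) -> bool:
        """Every fold trained without its held-out subject, exactly once."""
        if len(self.fold_train_subjects) != len(self.subjects):
            return False
        all_subj = set(self.subjects)
        return all(
            held not in train and set(train) == all_subj - {held}
            for held, train in zip(self.subjects, self.fold_train_subjects)
        )


def _confusion(labels, preds, classes) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(labels, preds):
        raw.loc[t, p] += 1
    norm = raw.div(raw.sum(axis=1).replace(0, 1), axis=0)
    return raw, norm


def _fit_binary(covs, labels, idx, classes, n_filters, shrinkage):
    a, b = classes
    models = {}
    for band in BAND_ORDER:
        models[band] = fit_csp(
            [covs[i][band] for i in idx if labels[i] == a],
            [covs[i][band] for i in idx if labels[i] == b],
            n_filters=n_filters, shrinkage=shrinkage,
        )
        models[band].classes = classes
        models[band].band = band
    X = np.array([csp_features(covs[i], models) for i in idx])
    return models, X


def losocv(
    covs: list[dict[str, np.ndarray]],
    labels,
    subjects: list | None = None,
    task: str = "binary",
    n_filters: int = 2,
    shrinkage: str | float = "lw",
    positive: object | None = None,
) -> DecodingResult:
    """Leave-one-subject-out CSP+LDA decoding.

    Every fold refits CSP filters and the LDA on the training subjects
    only; the held-out subject is projected through those fold-specific
    models, so no information leaks across folds.  ``task`` is 'binary'
    (one CSP model per band, 6 features) or 'three_class' (one-vs-one CSP
    features concatenated, 18 features, single multiclass LDA).
    """
    labels = np.asarray(labels)
    n = len(covs)
    if subjects is None:
        subjects = list(range(n))
    classes = tuple(sorted(set(labels.tolist())))
    if task == "binary" and len(classes) != 2:
        raise DecodingError("binary task needs exactly 2 classes")
    if task == "three_class" and len(classes) != 3:
        raise DecodingError("three_class task needs exactly 3 classes")
    if positive is None:
        positive = classes[0]

    preds, scores, fold_train = [], [], []
    for held in range(n):
        train = [i for i in range(n) if i != held]
        tlabels = labels[train]
        if len(set(tlabels.tolist())) != len(classes):
            raise DecodingError(f"fold {held}: a training fold lost a class entirely")
        if task == "binary":
            models, X = _fit_binary(covs, labels, train, classes, n_filters, shrinkage)
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                             priors=np.full(2, 0.5))
            clf.fit(X, tlabels)
            x = csp_features(covs[held], models)[None, :]
            pred = clf.predict(x)[0]
            dec = float(clf.decision_function(x)[0])
            # sklearn's decision function is positive toward classes_[1]
            score = dec if clf.classes_[1] == positive else -dec
        else:
            pair_models = []
            feats_train = []
            import itertools as _it
            for pair in _it.combinations(classes, 2):
                models, _ = _fit_binary(covs, labels, train, pair, n_filters, shrinkage)
                pair_models.append(models)
            X = np.array([
                np.concatenate([csp_features(covs[i], m) for m in pair_models])
                for i in train
            ])
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                             priors=np.full(len(classes), 1 / len(classes)))
            clf.fit(X, tlabels)
            x = np.concatenate([csp_features(covs[held], m) for m in pair_models])[None, :]
            pred = clf.predict(x)[0]
            score = float(clf.predict_proba(x).max())
        preds.append(pred)
        scores.append(score)
        fold_train.append([subjects[i] for i in train])

    preds = np.array(preds)
    scores = np.array(scores)
    accuracy = float(np.mean(preds == labels))
    auc = None
    roc_points = None
    if task == "binary":
        auc, roc_points = roc_auc(scores, labels, positive)
    raw, norm = _confusion(labels, preds, classes)
    return DecodingResult(
        subjects=list(subjects), labels=labels, predictions=preds, scores=scores,
        accuracy=accuracy, auc=auc, roc_points=roc_points,
        confusion=raw, confusion_normalized=norm, classes=classes,
        fold_train_subjects=fold_train,
    )


def csp_patterns_map(models: dict[str, CspModel], channels: list[str]) -> pd.DataFrame:
    """Pattern topographies rescaled to max |value| = 1 within each band."""
    rows = []
    for band, model in models.items():
        A = model.patterns.copy()
        scale = np.max(np.abs(A), axis=0)
        scale[scale == 0] = 1.0
        A = A / scale
        for comp in range(A.shape[1]):
            for ch, val in zip(channels, A[:, comp]):
                rows.append({"channel": ch, "band": band,
                             "component": comp, "value": float(val)})
    return pd.DataFrame(rows)
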