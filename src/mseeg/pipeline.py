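"""Pipeline orchestration, configuration, I/O and reporting.

``run_pipeline`` ties the stages together for a whole cohort:

    synthesize-or-load -> preprocess (notch, band-pass, clean 90-s
    segment, common average, flip) -> features (ROI band power + peak
    alpha, Laplacian ROI coherence, dirBSI) -> family statistics (HC vs P
    and subgroup omnibus with BH-FDR) -> CSP+LDA decoding -> report.

Every output table carries the configuration hash and package version.
Recordings round-trip through a float32 binary + JSON sidecar container;
EDF files are read through MNE when present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import subject_dirbsi
from .connectivity import roi_coherence_table
from .csd import build_spline_matrices, csd_transform
from .decoding import losocv, subject_covariances
from .montage import Montage, geodesic_montage
from .preprocess import (Recording, Segment, common_average,
                         extract_clean_segment, filter_chain, flip_hemispheres)
from .spectral import BAND_ORDER, BANDS, band_power, peak_alpha_frequency, welch_psd
from .stats import StatResult, family_fdr, omnibus_test, spearman, two_group_test
from .synth import CohortConfig, default_effects, generate_cohort

DECODING_TASKS = {
    "hcvp": ("HC", "P"),
    "p1p2": ("P1", "P2"),
    "p1p3": ("P1", "P3"),
    "p2p3": ("P2", "P3"),
    "three_class": ("P1", "P2", "P3"),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's stated values."""

    seed: int = 0
    group_sizes: dict = field(
        default_factory=lambda: {"HC": 22, "P1": 22, "P2": 18, "P3": 17}
    )
    fs: float = 250.0
    duration_s: float = 120.0  # recorded duration; segment_s seconds are extracted
    notch_hz: float = 50.0
    band: tuple = (0.5, 30.0)
    filter_order: int = 4
    threshold_uv: float = 100.0
    segment_s: float = 90.0
    csd_m: int = 4
    csd_lambda: float = 1e-5
    csd_n_terms: int = 50
    welch_window_s: float = 2.0
    welch_step_s: float = 1.0
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_filters: int = 2
    decoding_tasks: tuple = ("hcvp", "p1p2", "p1p3", "p2p3", "three_class")
    run_decoding: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        doc = json.loads(text)
        doc["band"] = tuple(doc.get("band", (0.5, 30.0)))
        doc["decoding_tasks"] = tuple(doc.get("decoding_tasks", ()))
        return cls(**doc)


# -- container I/O -------------------------------------------------------

def write_recording(rec: Recording, stem: str | Path) -> None:
    """float32 binary + JSON sidecar; values stored in uV."""
    stem = Path(stem)
    rec.data.astype("<f4").tofile(stem.with_suffix(".bin"))
    meta = {k: v for k, v in rec.meta.items() if k != "planted"}
    sidecar = {
        "channels": list(rec.channels), "fs": rec.fs,
        "n_samples": int(rec.data.shape[1]), "dtype": "<f4", "units": "uV",
        "meta": meta,
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read EDF (via MNE) or the binary + JSON container."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "raw+json"
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(raw.get_data() * 1e6, raw.info["sfreq"], raw.ch_names, {})
    stem = path.with_suffix("")
    with open(stem.with_suffix(".json")) as fh:
        sc = json.load(fh)
    data = np.fromfile(stem.with_suffix(".bin"), dtype=sc["dtype"])
    expected = len(sc["channels"]) * sc["n_samples"]
    if data.size != expected:
        raise PipelineError(
            f"truncated container: {data.size} values, expected {expected}"
        )
    data = data.reshape(len(sc["channels"]), sc["n_samples"]).astype(float)
    return Recording(data, sc["fs"], sc["channels"], sc.get("meta", {}))


# -- per-subject feature extraction -------------------------------------

def preprocess_recording(rec: Recording, config: PipelineConfig,
                         montage: Montage) -> Segment:
    filtered = filter_chain(rec, config.notch_hz, config.band, config.filter_order)
    seg = extract_clean_segment(filtered, config.threshold_uv, config.segment_s,
                                config.welch_window_s)
    seg = common_average(seg)
    side = rec.meta.get("lesion_side", "none")
    return flip_hemispheres(seg, side, montage)


def subject_features(
    seg: Segment, montage: Montage, config: PipelineConfig,
    csd_matrix: np.ndarray | None = None,
) -> dict[str, float]:
    """All univariate features of one preprocessed segment."""
    feats: dict[str, float] = {}
    index = {c: i for i, c in enumerate(seg.channels)}
    for roi in montage.rois:
        rows = [index[c] for c in montage.rois[roi]]
        series = seg.data[rows].mean(axis=0)
        est = welch_psd(series, seg.fs, config.welch_window_s, config.welch_step_s)
        for name in BAND_ORDER:
            feats[f"psd:{roi}:{name}"] = band_power(est, BANDS[name], in_db=True)
        feats[f"paf:{roi}"] = peak_alpha_frequency(est).paf_hz
    if csd_matrix is None:
        splines = build_spline_matrices(montage, config.csd_m, config.csd_n_terms)
        csd_matrix = csd_transform(splines, config.csd_lambda)
    lap = csd_matrix @ seg.data
    roi_series = {
        roi: lap[[index[c] for c in montage.rois[roi]]].mean(axis=0)
        for roi in montage.rois
    }
    table = roi_coherence_table(roi_series, seg.fs, BANDS,
                                config.welch_window_s, config.welch_step_s)
    for _, row in table.iterrows():
        feats[f"fc:{row.roi_a}-{row.roi_b}:{row.band}"] = row.coherence
    bsi = subject_dirbsi(seg.data, list(seg.channels), montage, seg.fs)
    for name in BAND_ORDER:
        feats[f"dirbsi:{name}"] = bsi[name]
    feats["dirbsi:full"] = bsi["full"]
    return feats


# -- cohort statistics ---------------------------------------------------

def cohort_statistics(features: pd.DataFrame, alpha: float = 0.05,
                      fdr_q: float = 0.05) -> pd.DataFrame:
    """HC-vs-P and subgroup omnibus tests with family-wise BH correction."""
    fam_of = lambda col: col.split(":")[0]
    feature_cols = [c for c in features.columns
                    if fam_of(c) in ("psd", "fc", "dirbsi", "paf")
                    and not c.endswith(":full")]
    is_patient = features.group != "HC"
    results: list[StatResult] = []
    sub_results: list[StatResult] = []
    for col in feature_cols:
        hc = features.loc[~is_patient, col].to_numpy()
        pa = features.loc[is_patient, col].to_numpy()
        if hc.size >= 4 and pa.size >= 4:
            results.append(two_group_test(hc, pa, alpha, feature=col, family=fam_of(col)))
        groups = {
            g: features.loc[features.group == g, col].to_numpy()
            for g in ("P1", "P2", "P3") if (features.group == g).sum() >= 4
        }
        if len(groups) == 3:
            sub_results.append(omnibus_test(groups, alpha, feature=col, family=fam_of(col)))
    family_fdr(results, fdr_q)
    family_fdr(sub_results, fdr_q)
    rows = []
    for contrast, rs in (("HCvsP", results), ("P1P2P3", sub_results)):
        for r in rs:
            row = {
                "contrast": contrast, "feature": r.feature, "family": r.family,
                "test": r.test, "statistic": r.statistic, "p": r.p, "q": r.q,
                "reject": r.reject,
            }
            for gname, s in r.group_summaries.items():
                row[f"mean_{gname}"] = s["mean"]
                row[f"sd_{gname}"] = s["sd"]
            rows.append(row)
    return pd.DataFrame(rows)


def behavior_correlations(features: pd.DataFrame, fdr_q: float = 0.05,
                          scales: tuple = ("MMT", "FMA", "MMSE", "ADL")) -> pd.DataFrame:
    """Spearman EEG-behavior correlations, BH-corrected per scale."""
    rows = []
    patients = features[features.group != "HC"]
    feature_cols = [c for c in features.columns
                    if c.split(":")[0] in ("psd", "fc", "dirbsi", "paf")
                    and not c.endswith(":full")]
    for scale in scales:
        if scale not in patients.columns:
            continue
        y = patients[scale].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 5:
            continue
        scale_rows = []
        for col in feature_cols:
            x = patients[col].to_numpy(float)[ok]
            r = spearman(x, y[ok])
            if not r.undefined:
                scale_rows.append({"scale": scale, "feature": col,
                                   "rho": r.rho, "p": r.p, "n": r.n})
        if scale_rows:
            from .stats import bh_fdr

            qvals, rej = bh_fdr([r["p"] for r in scale_rows], fdr_q)
            for row, qv, rj in zip(scale_rows, qvals, rej):
                row["q"] = float(qv)
                row["reject"] = bool(rj)
            rows.extend(scale_rows)
    return pd.DataFrame(rows)


# -- decoding over the cohort -------------------------------------------

def cohort_decoding(
    segments: list[Segment], manifest: pd.DataFrame, config: PipelineConfig,
    tasks: tuple | None = None,
) -> dict:
    covs = [subject_covariances(s.data, s.fs) for s in segments]
    labels = manifest.group.to_numpy()
    subjects = manifest.subject_id.tolist()
    out = {}
    for task in (tasks or config.decoding_tasks):
        members = DECODING_TASKS[task]
        if task == "hcvp":
            tl = np.where(labels == "HC", "HC", "P")
            mask = np.ones(len(labels), bool)
        else:
            tl = labels
            mask = np.isin(labels, members)
        idx = np.where(mask)[0]
        kind = "three_class" if task == "three_class" else "binary"
        out[task] = losocv(
            [covs[i] for i in idx], tl[idx], [subjects[i] for i in idx],
            task=kind, n_filters=config.n_filters, positive=members[0],
        )
    return out


# -- orchestration -------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 montage: Montage | None = None) -> Path:
    """Execute the full synthetic-cohort pipeline into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    montage = montage or geodesic_montage()
    log_path = outdir / "log.jsonl"
    cfg_hash = config.hash()

    def log(stage, **kw):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "t": time.time(),
                                 "config": cfg_hash, **kw}) + "\n")

    (outdir / "config.json").write_text(config.to_json())
    log("config", version=__version__)

    cohort_cfg = CohortConfig(group_sizes=dict(config.group_sizes), fs=config.fs,
                              duration_s=config.duration_s, seed=config.seed)
    t0 = time.time()
    recordings, manifest = generate_cohort(cohort_cfg, default_effects(), montage)
    log("synth", n=len(recordings), seconds=time.time() - t0)

    splines = build_spline_matrices(montage, config.csd_m, config.csd_n_terms)
    csd_matrix = csd_transform(splines, config.csd_lambda)

    t0 = time.time()
    segments, feat_rows = [], []
    for rec in recordings:
        sid = rec.meta.get("subject_id", "?")
        try:
            seg = preprocess_recording(rec, config, montage)
            feats = subject_features(seg, montage, config, csd_matrix)
        except Exception as err:
            raise PipelineError(f"stage failed for subject {sid}: {err}") from err
        segments.append(seg)
        feats["subject_id"] = sid
        feat_rows.append(feats)
    features = manifest.merge(pd.DataFrame(feat_rows), on="subject_id")
    log("features", seconds=time.time() - t0)

    def _save(df: pd.DataFrame, name: str):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# mseeg {__version__} config {cfg_hash}\n")
            df.to_csv(fh, sep="\t", index=False)

    _save(manifest, "manifest.tsv")
    _save(features, "features.tsv")
    long_rows = []
    for _, row in features.iterrows():
        for col in features.columns:
            if ":" in str(col):
                kind, *rest = col.split(":")
                long_rows.append({"subject_id": row.subject_id, "feature": col,
                                  "kind": kind, "value": row[col]})
    _save(pd.DataFrame(long_rows), "features_long.tsv")

    t0 = time.time()
    stats_df = cohort_statistics(features, config.alpha, config.fdr_q)
    _save(stats_df, "stats.tsv")
    behav = behavior_correlations(features, config.fdr_q)
    if not behav.empty:
        _save(behav, "behavior_correlations.tsv")
    log("stats", seconds=time.time() - t0)

    if config.run_decoding:
        t0 = time.time()
        decoding = cohort_decoding(segments, manifest, config)
        metrics = {}
        for task, res in decoding.items():
            metrics[task] = {
                "accuracy": res.accuracy, "auc": res.auc,
                "n_subjects": len(res.subjects),
                "leakage_audit_passed": res.audit_no_leakage(),
            }
            _save(pd.DataFrame({"subject_id": res.subjects,
                                "label": res.labels, "prediction": res.predictions,
                                "score": res.scores}), f"predictions_{task}.tsv")
            _save(res.confusion.reset_index(names="true"), f"confusion_{task}.tsv")
            if res.roc_points is not None:
                _save(res.roc_points, f"roc_{task}.tsv")
        (outdir / "decoding.json").write_text(
            json.dumps({"version": __version__, "config": cfg_hash,
                        "tasks": metrics}, indent=1))
        log("decoding", seconds=time.time() - t0)

    write_report(outdir)
    log("done")
    return outdir


def write_report(run_dir: str | Path) -> Path:
    """Regenerate the human-readable summary from a run directory alone."""
    run_dir = Path(run_dir)
    feats = pd.read_csv(run_dir / "features.tsv", sep="\t", comment="#")
    stats_df = pd.read_csv(run_dir / "stats.tsv", sep="\t", comment="#")
    lines = ["# Cohort summary", ""]
    counts = feats.group.value_counts().to_dict()
    lines.append("Group sizes: " + ", ".join(f"{g}={counts[g]}" for g in sorted(counts)))
    lines.append("")
    lines.append("## Group means +- SD (selected features)")
    sel = [c for c in feats.columns if str(c).startswith(("psd:", "dirbsi:", "paf:"))]
    for col in sel[:40]:
        parts = []
        for g in sorted(counts):
            v = feats.loc[feats.group == g, col]
            parts.append(f"{g}: {v.mean():+.2f}+-{v.std():.2f}")
        lines.append(f"{col:24s} " + "  ".join(parts))
    lines.append("")
    surv = stats_df[stats_df.reject.fillna(False)]
    lines.append(f"## FDR survivors (q <= 0.05): {len(surv)}")
    for _, r in surv.iterrows():
        lines.append(f"  {r.contrast:8s} {r.feature:24s} {r.test:20s} "
                     f"p={r.p:.2e} q={r.q:.3f}")
    dec_path = run_dir / "decoding.json"
    if dec_path.exists():
        doc = json.loads(dec_path.read_text())
        lines.append("")
        lines.append("## Decoding (leave-one-subject-out)")
        for task, m in doc["tasks"].items():
            auc = "n/a" if m["auc"] is None else f"{m['auc']:.3f}"
            lines.append(f"  {task:12s} accuracy={100 * m['accuracy']:.2f}%  "
                         f"AUC={auc}  n={m['n_subjects']}")
    report = run_dir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
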