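# Methods

`mseeg` implements a multi-scale analysis of resting-state, eyes-open EEG
for lesion-stratified stroke cohorts: local oscillatory power, peak alpha
frequency (PAF), surface-Laplacian-based inter-regional coherence, a
directional brain symmetry index (dirBSI), family-structured group
statistics, and CSP+LDA lesion-subtype decoding.  Because no clinical
recordings are distributed with the package, a synthetic-cohort generator
produces surrogate data that carry the group-level effect structure the
analysis is designed to detect; every quantitative claim in the test
suite is a property of the implementation evaluated on those surrogates.

## Montage and regions of interest

The packaged montage is the idealized 129-channel geodesic sensor net
(E1..E128 plus the Cz reference site).  Positions are taken at runtime
from MNE-Python's standard layout, centered by a least-squares sphere fit
and normalized to the unit sphere — coherence and dirBSI are invariant to
global amplitude and head-radius scaling, so no physical radius is
carried.  Six ROIs are fixed electrode lists: frontal (F), "affected"
motor (AM), central (C), "unaffected" motor (UM), parietal (P) and
occipital (O); the AM/UM labels acquire their ipsi-/contralesional meaning
only after hemisphere flipping.  ROI lists are validated but their
disjointness is verified, not assumed (`Montage.roi_overlap`).

Homologous left–right pairs are computed geometrically: a channel is
paired with the unique channel within 3° (great circle) of its sagittal
mirror image; self-mirroring channels are midline.  On the packaged
layout this yields exactly 59 pairs and 11 midline channels, and the test
suite cross-checks the matcher against a brute-force nearest-neighbour
oracle.  Pairing is ambiguous only if two candidates fall inside the
tolerance, which is an error, never a silent choice.

## Preprocessing

The fixed chain is: 50 Hz notch (second-order IIR, Q = 30) → 0.5–30 Hz
fourth-order Butterworth band-pass, both applied forward–backward (zero
phase, standard for offline spectral work) → extraction of the earliest
90 s of clean signal, scanning non-overlapping 2-s windows and discarding
any window whose absolute amplitude exceeds 100 µV on any channel →
common-average reference → channel flip for left-lesion subjects, which
permutes each pair's rows so all lesions align to a right-hemisphere
model.  The flip is an involution and commutes with the common average (a
permutation preserves the per-sample channel mean); both facts are
asserted in tests.  The amplitude criterion is applied after filtering,
i.e. to the analysis-band signal.  An optional "abnormal spectral
characteristics" flag (window broadband power > 5 robust SDs above the
recording median) is provided but off by default, as no quantitative
criterion is standard.  Ocular-artifact decomposition is out of scope for
synthetic data without ocular sources; the amplitude threshold plus a
pluggable rejection hook stand in its place.

## Spectral features

All spectra are Welch estimates with 2-s Hamming windows advanced in 1-s
steps (89 windows per 90-s segment), one-sided density scaling, no
detrending — so the estimate is exactly quadratic in the input and the
scaling/concatenation identities in the tests hold to machine precision.
Band power is the trapezoidal integral of the linear PSD over θ (4–7),
α (7–12) or β1 (12–16 Hz), reported in dB via Y = 10·log10 X; non-positive
power is an error, never clipped.  Trapezoid integrals over contiguous
bands are additive, so the three bands partition the 4–16 Hz integral
exactly.  Wherever discrete bins are selected (PAF search, coherence band
means, dirBSI bins) shared edges are assigned half-open, [lo, hi).  PSD
features are computed on ROI-averaged, common-average-referenced signals
(signal-domain averaging first); PAF is the frequency of the maximum bin
in [7, 12] with ties broken downward and a "no peak" flag when the
maximum sits on a boundary of a monotone spectrum.  δ-band analysis is
deliberately excluded.

## Surface Laplacian and coherence

The current-source-density transform uses spherical splines with
stiffness m = 4 and a 50-term Legendre series (the tail beyond 50 terms
changes G by < 1e-10).  The regularized system (G + λI), λ = 1e-5, is
solved under the sum-to-zero constraint on spline coefficients via the
Schur complement of the bordered (Lagrange) system, and the output is the
H-weighted coefficient vector.  Output units on the unit sphere are
arbitrary; magnitude-squared coherence is invariant to them.  A dense
bordered-matrix inversion serves as the independent oracle in tests
(agreement to 1e-6 relative on a 16-channel montage).  The Laplacian is
applied channel-wise before ROI averaging, only in the connectivity path;
PSD and dirBSI use non-Laplacian signals.

Coherence C_XY(f) = |P_XY|²/(P_XX·P_YY) uses the same Welch segmentation;
the band summary is the mean of per-bin coherence over band bins (the
alternative, coherence of band-integrated spectra, is nonstandard and was
rejected).  With K averaged windows the estimator is biased upward by
≈1/K under independence; at least 8 windows are required and fewer than
20 warn.  Six ROIs yield 15 unordered pairs × 3 bands = 45 entries.

## Directional brain symmetry index

dirBSI = Σ(R − L) / Σ(R + L) over the 59 homologous pairs and integer-Hz
bins 4..16, where R/L is the Welch spectral power (µV²/Hz) of the right-
and left-hemisphere pair members; an amplitude variant is switchable.
Values lie in [−1, 1]; positive means right-hemisphere — after flipping,
ipsilesional — predominance.  Band-restricted variants sum over the
band's integer bins (θ 4–6, α 7–11, β1 12–15); the full-range variant
(all 13 bins) is also reported.  The index is exactly antisymmetric under
hemisphere exchange and scale-invariant, both property-tested.  Patients
are flipped before the computation; controls have no lesion side and are
never flipped.

## Statistics

Each feature's two-group comparison (controls vs patients) branches on
the Lilliefors normality test at 0.05 in both groups: pooled-variance
t-test if both pass, Wilcoxon rank-sum otherwise (exact enumeration p
when samples are small and tie-free).  Three-group lesion comparisons
branch the same way between one-way ANOVA and Kruskal–Wallis, with post
hoc pairwise tests labeled exploratory whenever the omnibus is not
significant.  Benjamini–Hochberg step-up FDR at q = 0.05 is applied
within families: 18 PSD features (3 bands × 6 ROIs), 45 coherences, 3
dirBSI values, and 6 ROI-level PAF tests — only one ROI's PAF contrast is
of primary interest, but all six are tested and corrected rather than
selectively reported.  EEG–behavior associations use Spearman rank
correlation (exact permutation p for n ≤ 9) with a separate BH family per
behavioral scale.  The minimum group size is 4 (a Lilliefors
requirement).

## Decoding

One covariance per subject per band is computed from the full 90-s
band-filtered segment and trace-normalized; the subject is the trial, so
leave-one-subject-out cross-validation yields exactly one decision per
subject.  CSP solves Σ_A w = λ(Σ_A + Σ_B)w, keeping the eigenvectors at
the largest and smallest eigenvalues; features are log(wᵀΣw), 6 per
binary model.  Because channel count (128+) far exceeds subjects per
class, class-mean covariances are shrunk toward the scaled identity with
a Ledoit-Wolf-style intensity estimated from the between-subject matrix
dispersion.  Patterns (for topographic display) are the corresponding
columns of the inverse-transpose of the full filter basis, rescaled to
max |value| = 1 per band for visualization only.  The classifier is LDA
(lsqr solver, shrinkage-regularized pooled covariance) with uniform class
priors — a balanced decision rule chosen because leave-one-out folds are
inherently imbalanced, which would otherwise bias null (permuted-label)
accuracy below chance.  Three-class decoding concatenates the three
one-vs-one CSP feature blocks (18 features) into one multiclass LDA; a
vote-fusion alternative was considered and rejected as harder to
calibrate.  Every fold refits CSP and LDA on training subjects only, and
each result object carries fold provenance for a no-leakage audit.  CSP
features are not standardized before LDA (LDA is affine-equivariant up to
the shrinkage term).

## Synthetic cohorts

The generator emulates a 4-group cohort (HC = 22, P1 = 22, P2 = 18,
P3 = 17; half of each patient group left-lesioned) of 120-s recordings
at 250 Hz, from which the pipeline extracts the 90-s analysis segment —
recording longer than the target leaves margin for threshold-rejected
windows, as a real session does.  The analysis tops out at 16 Hz, so
250 Hz comfortably satisfies Nyquist while keeping desk-scale runtime;
any rate ≥ 250 Hz works.
Each subject is synthesized in the frequency domain as:

* per-channel 1/f^γ Gaussian background (γ = 1, PSD 6e-4 µV²/Hz at 1 Hz);
* one band-limited oscillator source per ROI and band, placed at the ROI
  centroid and spread to all electrodes by an exponential
  distance-decay kernel exp(−d/0.35 rad) — a deliberately simple
  volume-conduction surrogate that gives the Laplacian smooth topography
  to sharpen and creates known cross-ROI leakage;
* a Gaussian alpha peak (σ = 0.5 Hz) at the subject's drawn PAF riding on
  a cosine-tapered broadband floor; all band envelopes are tapered and
  inset 0.25 Hz from the band edges so the 2-s Welch window cannot smear
  a spectral cliff across the shared 7-Hz edge into the PAF search;
* per-band hemispheric amplitude gains planting the drawn dirBSI; the
  gain is solved against the post-common-average expected channel band
  powers, because the common average subtracts a hemispherically
  symmetric component that would otherwise dilute a naive power-ratio
  gain by 10–18%;
* a full source covariance per band whose off-diagonal entries are solved
  numerically so that the *measured* band-mean coherence of the analysis
  path (Laplacian → ROI average → Welch, including kernel leakage, the
  background floor, and the known ≈(1−C)²/K_eff estimator bias) hits the
  drawn per-subject target; the joint matrix must be positive
  semidefinite, with mild tail violations projected back to the cone.

Per-subject feature values are drawn from group-level normal
distributions whose default means and SDs are the study-condition
targets (e.g. PAF 9.93 ± 1.09 Hz in controls vs 8.75 ± 1.02 Hz in
patients; ipsilesional-motor alpha power −14.89 ± 7.88 vs −4.36 ± 9.10
dB; θ dirBSI −0.026 ± 0.101 vs +0.061 ± 0.122; θ fronto-motor coherence
0.100 vs 0.136; parieto-occipital coherence 0.274 vs 0.222 in α and
0.225 vs 0.187 in β1; subgroup-specific α dirBSI and parietal β1 power).
Cells without published values are filled with typical resting-EEG
levels and symmetric motor-region defaults.  The printed ± values are
group-level SDs; within-subject variability is not reported anywhere, so
the generator treats the drawn value as the subject's noiseless target —
an explicit assumption.  Band-power deviations within a subject share a
global component (loading 0.95) because most between-subject power
variance is a whole-head gain; the homologous motor ROIs share their
residual so the hemispheric base stays symmetric and dirBSI is set by
the planted gain alone.  Fully independent cell draws with 8–9 dB SDs
would produce 30-dB within-subject cliffs between neighbouring ROIs and
bands — unphysiological, and they would drown both the planted
asymmetries and the coherence targets in leakage.  Deviations are
winsorized (global at ±2 SD, residual at ±2.5 SD; marginal SD ≈ 0.96 of
nominal): real band powers are bounded, and an unbounded +3 SD
whole-head draw would exceed the ±100 µV screening threshold in every
window — a recording that would never enter a cohort.

Power calibration solves nonnegative least squares on the squared
(common-average-referenced) mixing gains; a target that falls below a
neighbour's leakage floor clamps that source to zero (the ROI then sits
at the floor), and a target below the background floor is a hard error.
Left-lesion subjects are generated in the canonical lesion-right space
and returned mirrored, so the preprocessing flip restores exactly what
was planted.  All randomness descends from one root seed through spawned
per-subject generators; identical seeds give bit-identical recordings.

Behavioral scores (MMT, FMA, MMSE, modified Barthel ADL) are drawn from
group-level distributions and coupled (ρ = 0.5) to the subject's
motor-alpha power deviation, so the Spearman stage has real signal;
scores are clipped to their instrument ranges.

What the generator does **not** emulate: realistic biophysical forward
models, ocular/muscle artifact morphology (only amplitude transients),
non-stationarity within the 90 s, line-noise harmonics, inter-electrode
impedance differences, or any true lesion physiology.  Passing recovery
tests therefore demonstrates that the pipeline measures what it claims
to measure under its own assumptions — not that those effects would be
found in real patients.

## Problem sizes and numerical choices

Recovery tests run 20 cohorts of 79 subjects (90 s at 250 Hz) through
the full signal path for PAF, θ-dirBSI and coherence; statistical power
and null calibration (100 and 200 cohorts) run at the feature level,
drawing from the same planted distributions the synthesis realizes —
the signal path adds only runtime there, not information.  Decoding
sanity checks use 32-channel constructions.  Tolerances: PAF group means
within ±0.5 Hz (one Welch bin), coherence group means within ±0.05,
dirBSI ordering in ≥90% of cohorts, CSP/Laplacian/BH oracle agreement at
1e-8/1e-6/exact.  Degenerate inputs (constant spectra, zero
denominators, rank-deficient covariances, coincident electrodes, folds
that lose a class) raise explicit errors rather than propagating NaNs.

## Known limitations

EDF export is not provided (recordings round-trip through a float32 +
JSON sidecar container; EDF files can be read if present).  The theta
and beta band-power estimates carry a small negative bias (≈0.5–1.5 dB)
from Welch smearing at band edges; it is identical across groups and
does not affect contrasts.  The ROI lists of the "affected" and
"unaffected" motor regions are treated as authoritative configuration;
their physical hemisphere assignment under the geodesic layout is left
as configured.  Coherence values are planted per subject as targets of a
calibrated generator, not an exact spectral model; agreement is
validated at the ±0.05 group-mean level, not per subject.
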