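"""Normality-branched group statistics with family-wise FDR control.

Each feature is tested with an independent-samples t-test (pooled
variance) when both groups pass the Lilliefors normality test at 0.05,
otherwise with the Wilcoxon rank-sum (Mann-Whitney) test; three-group
comparisons branch between one-way ANOVA and Kruskal-Wallis the same way.
p-values are corrected with the Benjamini-Hochberg step-up procedure
within predefined analysis families: 18 PSD features (3 bands x 6 ROIs),
45 coherences (3 bands x 15 ROI pairs), 3 dirBSI values (one per band),
and 6 ROI-level peak-alpha frequencies.  EEG-behavior associations use
Spearman rank correlation with its own family per behavioral scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .montage import ROI_IDS
from .spectral import BAND_ORDER

MIN_N = 4  # Lilliefors needs at least 4 observations


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    feature: str
    family: str
    test: str
    statistic: float
    p: float
    q: float | None = None
    reject: bool | None = None
    normality: dict = field(default_factory=dict)
    group_summaries: dict = field(default_factory=dict)
    posthoc: list = field(default_factory=list)
    exploratory: bool = False


def is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Lilliefors test for normality (True = cannot reject normality)."""
    x = np.asarray(x, float)
    if x.size < MIN_N:
        raise StatsError(f"Lilliefors requires n >= {MIN_N}, got {x.size}")
    if np.ptp(x) == 0:
        return False  # degenerate sample: treat as non-normal
    _, p = lilliefors(x, dist="norm")
    return p > alpha


def _summary(x: np.ndarray) -> dict:
    return {"n": int(x.size), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}


def _ranksum(a: np.ndarray, b: np.ndarray):
    """Wilcoxon rank-sum via Mann-Whitney U; exact when feasible (no ties,
    small samples), otherwise the tie-corrected normal approximation."""
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_group_test(
    a, b, alpha: float = 0.05, feature: str = "", family: str = "", force: str | None = None
) -> StatResult:
    """HC-vs-P style comparison with the normality branch recorded.

    ``force`` overrides the branch ('t' or 'ranksum') for calibration and
    oracle tests; by default the branch follows the Lilliefors outcome.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if force is None:
        if min(a.size, b.size) < MIN_N:
            raise StatsError(f"each group needs n >= {MIN_N}")
        norm_a, norm_b = is_normal(a, alpha), is_normal(b, alpha)
        branch = "t" if (norm_a and norm_b) else "ranksum"
    else:
        # forced branch: the normality pre-test is bypassed
        norm_a = norm_b = None
        branch = force
        if min(a.size, b.size) < 2:
            raise StatsError("each group needs n >= 2")
    if branch == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t (pooled)"
    elif branch == "ranksum":
        stat, p = _ranksum(a, b)
        test = "wilcoxon rank-sum"
    else:
        raise StatsError(f"unknown branch {branch!r}")
    return StatResult(
        feature=feature, family=family, test=test,
        statistic=float(stat), p=float(p),
        normality={"a": norm_a, "b": norm_b},
        group_summaries={"a": _summary(a), "b": _summary(b)},
    )


def omnibus_test(
    groups: dict[str, np.ndarray], alpha: float = 0.05,
    feature: str = "", family: str = "", force: str | None = None,
) -> StatResult:
    """ANOVA / Kruskal-Wallis across >= 3 groups with branched post hocs.

    Post hoc pairwise tests (same branching rules) always run; when the
    omnibus p is not below ``alpha`` they are labeled exploratory and
    should be read as uncorrected trends only.
    """
    if len(groups) < 3:
        raise StatsError("omnibus test needs at least 3 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if force is None:
        for k, v in arrays.items():
            if v.size < MIN_N:
                raise StatsError(f"group {k} needs n >= {MIN_N}")
        normality = {k: is_normal(v, alpha) for k, v in arrays.items()}
        branch = "anova" if all(normality.values()) else "kruskal"
    else:
        normality = {}
        branch = force
    vals = list(arrays.values())
    if branch == "anova":
        stat, p = sps.f_oneway(*vals)
        test = "one-way ANOVA"
    elif branch == "kruskal":
        stat, p = sps.kruskal(*vals)
        test = "kruskal-wallis"
    else:
        raise StatsError(f"unknown branch {branch!r}")
    exploratory = not (p < alpha)
    pair_force = None if force is None else ("t" if branch == "anova" else "ranksum")
    posthoc = []
    for ka, kb in itertools.combinations(arrays, 2):
        r = two_group_test(arrays[ka], arrays[kb], alpha, force=pair_force,
                           feature=f"{feature}:{ka}vs{kb}", family=family)
        r.exploratory = exploratory
        posthoc.append(r)
    return StatResult(
        feature=feature, family=family, test=test,
        statistic=float(stat), p=float(p),
        normality=normality,
        group_summaries={k: _summary(v) for k, v in arrays.items()},
        posthoc=posthoc, exploratory=exploratory,
    )


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags.

    q_i = min_{j >= i} (m * p_(j) / j) in sorted order, mapped back to the
    original order; rejection where q <= the target level.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    undefined: bool = False  # constant input


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p is exact (full permutation enumeration) for n <= 9 with no
    need for ties handling beyond average ranks; larger samples use the
    t-distribution approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise StatsError("spearman needs equal-length inputs with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, int(x.size), undefined=True)
    rho, p_approx = sps.spearmanr(x, y)
    n = x.size
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = np.array([np.corrcoef(rx, ry[pi])[0, 1] for pi in perms])
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = float(p_approx)
    return SpearmanResult(float(rho), p, int(n))


# -- analysis families ---------------------------------------------------

FAMILY_SIZES = {"psd": 18, "fc": 45, "dirbsi": 3, "paf": 6}


def assemble_families(feature_columns: list[str]) -> dict[str, list[str]]:
    """Partition feature ids into the predefined analysis families.

    Feature ids follow the pipeline conventions: ``psd:ROI:band``,
    ``fc:ROIa-ROIb:band``, ``dirbsi:band``, ``paf:ROI``.  Raises naming
    any expected feature that is missing and asserts the family sizes
    (18 / 45 / 3 / 6).
    """
    expected: dict[str, list[str]] = {"psd": [], "fc": [], "dirbsi": [], "paf": []}
    for roi in ROI_IDS:
        for band in BAND_ORDER:
            expected["psd"].append(f"psd:{roi}:{band}")
    for a, b in itertools.combinations(ROI_IDS, 2):
        for band in BAND_ORDER:
            expected["fc"].append(f"fc:{a}-{b}:{band}")
    expected["dirbsi"] = [f"dirbsi:{band}" for band in BAND_ORDER]
    expected["paf"] = [f"paf:{roi}" for roi in ROI_IDS]

    have = set(feature_columns)
    for fam, feats in expected.items():
        missing = [f for f in feats if f not in have]
        if missing:
            raise StatsError(f"family {fam} missing features: {missing}")
        assert len(feats) == FAMILY_SIZES[fam]
    return expected


def family_fdr(results: list[StatResult], q: float = 0.05) -> None:
    """In-place BH adjustment within each family present in ``results``."""
    by_family: dict[str, list[StatResult]] = {}
    for r in results:
        by_family.setdefault(r.family, []).append(r)
    for fam_results in by_family.values():
        qvals, rej = bh_fdr([r.p for r in fam_results], q)
        for r, qv, rj in zip(fam_results, qvals, rej):
            r.q = float(qv)
            r.reject = bool(rj)
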