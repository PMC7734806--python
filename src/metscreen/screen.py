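"""Per-feature two-group screening with adaptive test selection.

The decision tree mirrors a four-scenario protocol:

1. test each sample for normality (Anderson-Darling);
2. if both normal, compare variances (two-sided F): equal variances ->
   pooled Student t (``t_eq``), unequal -> Welch (``t_neq``);
3. if either sample non-normal, compare shapes (two-sample KS on
   median-centered samples): same shape -> Mann-Whitney U (``mw``),
   different shapes -> Welch applied anyway (``t_neq_dagger``).

Robustness of each p-value is scored by a leave-k-out resampling "FDR":
the fraction of recomputed p-values (over every deletion of 1, 2, ...
participants from the pooled cohort) that FAIL the significance level.  A
feature is flagged significant when p <= alpha and FDR <= fdr_threshold.

The test statistics are computed with hand-vectorized numpy/scipy.special
primitives because the resampling loop evaluates the full decision tree
thousands of times per feature; unit tests pin them against the
general-purpose scipy.stats implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from metscreen.cohort import CohortMatrix

SCENARIOS = ("t_eq", "t_neq", "mw", "t_neq_dagger", "chi2")

# 5%-level Anderson-Darling critical value (normal family, both parameters
# estimated): A2_crit = _AVAL / (1 + 0.75/n + 2.25/n^2), as tabulated by
# Stephens and used by scipy.stats.anderson.
_AVALS = {0.15: 0.561, 0.10: 0.631, 0.05: 0.752, 0.025: 0.873, 0.01: 1.035}

MIN_SAMPLE = 4


class ScreenError(ValueError):
    """Raised for invalid screening inputs."""


@dataclass
class UnivariateResult:
    """One feature's univariate screening record."""

    feature: str
    scenario: str
    statistic: float
    p: float
    fdr: float
    auc: float
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    ratio: float
    significant: bool


# -- building-block statistics -------------------------------------------------


def anderson_darling_a2(x: np.ndarray) -> float:
    """Anderson-Darling A^2 against a normal with estimated mean/sd."""
    n = x.size
    if n < MIN_SAMPLE:
        raise ScreenError(f"Anderson-Darling needs n >= {MIN_SAMPLE}, got {n}")
    y = np.sort(x)
    s = y.std(ddof=1)
    if s == 0:
        return math.inf
    w = (y - y.mean()) / s
    logcdf = special.log_ndtr(w)
    logsf = special.log_ndtr(-w)
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2 * i - 1.0) / n * (logcdf + logsf[::-1])))


def anderson_darling_critical(n: int, alpha: float = 0.05) -> float:
    if alpha not in _AVALS:
        raise ScreenError(f"no Anderson-Darling critical value tabulated for alpha={alpha}")
    return _AVALS[alpha] / (1.0 + 0.75 / n + 2.25 / n**2)


def f_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided variance-ratio F test p-value."""
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return 1.0
    if vy == 0.0 or vx == 0.0:
        return 0.0
    f = vx / vy
    dfn, dfd = x.size - 1, y.size - 1
    cdf = special.fdtr(dfn, dfd, f)
    sf = special.fdtrc(dfn, dfd, f)
    return float(min(1.0, 2.0 * min(cdf, sf)))


def ks_same_shape_p(x: np.ndarray, y: np.ndarray) -> float:
    """Asymptotic two-sample KS p on median-centered samples.

    Centering each sample at its median makes the test sensitive to shape
    (spread, skew, tails) but not to a pure location shift, which is what
    "same shape" has to mean ahead of a rank test for a location effect.
    """
    xc = np.sort(x - np.median(x))
    yc = np.sort(y - np.median(y))
    n1, n2 = xc.size, yc.size
    pooled = np.concatenate([xc, yc])
    cdf1 = np.searchsorted(xc, pooled, side="right") / n1
    cdf2 = np.searchsorted(yc, pooled, side="right") / n2
    d = np.abs(cdf1 - cdf2).max()
    en = math.sqrt(n1 * n2 / (n1 + n2))
    return float(min(1.0, special.kolmogorov(en * d)))


def _t_p(t: float, df: float) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    d = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        return (0.0, 1.0) if d == 0.0 else (math.inf * np.sign(d), 0.0)
    t = d / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), _t_p(t, n1 + n2 - 2)


def pooled_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled two-sample t from summary statistics (means, sds, sizes)."""
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    d = mean1 - mean2
    if sp2 == 0.0:
        return (0.0, 1.0) if d == 0.0 else (math.inf * np.sign(d), 0.0)
    t = d / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), _t_p(t, n1 + n2 - 2)


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
    d = x.mean() - y.mean()
    if v1 + v2 == 0.0:
        return (0.0, 1.0) if d == 0.0 else (math.inf * np.sign(d), 0.0)
    t = d / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), _t_p(t, df)


def _rankdata(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks plus the tie-correction term sum(t^3 - t)."""
    order = np.argsort(z, kind="mergesort")
    zs = z[order]
    boundary = np.empty(z.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = zs[1:] != zs[:-1]
    group = np.cumsum(boundary) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    starts = ends - counts
    midranks_per_group = (starts + ends + 1) / 2.0
    ranks = np.empty(z.size)
    ranks[order] = midranks_per_group[group]
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_term


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U statistic for x and normal-approximation two-sided p.

    Uses mid-ranks, the tie-corrected variance and a 0.5 continuity
    correction (matching ``scipy.stats.mannwhitneyu(method='asymptotic')``).
    """
    n1, n2 = x.size, y.size
    ranks, tie_term = _rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        return float(u1), 1.0
    num = abs(u1 - mu) - 0.5  # continuity correction
    z = max(num, 0.0) / math.sqrt(var)
    return float(u1), float(min(1.0, 2.0 * special.ndtr(-z)))


# -- adaptive selection --------------------------------------------------------


def _scenario(x: np.ndarray, y: np.ndarray, alpha: float, warn: bool = True) -> str:
    nx, ny = x.size, y.size
    if nx < MIN_SAMPLE or ny < MIN_SAMPLE:
        raise ScreenError(f"samples too small for test selection ({nx} vs {ny})")
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        if warn:
            warnings.warn("constant sample: normality undefined, falling back to Mann-Whitney")
        return "mw"
    normal_x = anderson_darling_a2(x) <= anderson_darling_critical(nx, alpha)
    normal_y = anderson_darling_a2(y) <= anderson_darling_critical(ny, alpha)
    if normal_x and normal_y:
        return "t_neq" if f_test_p(x, y) < alpha else "t_eq"
    return "t_neq_dagger" if ks_same_shape_p(x, y) < alpha else "mw"


def select_test(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> str:
    """Choose the two-sample scenario for the given samples.

    Returns one of ``t_eq``, ``t_neq``, ``mw``, ``t_neq_dagger``.
    """
    return _scenario(np.asarray(x, dtype=float), np.asarray(y, dtype=float), alpha)


def two_sample_p(x: Sequence[float], y: Sequence[float], scenario: str) -> tuple[float, float]:
    """(statistic, two-sided p) for the given scenario."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if scenario == "t_eq":
        return _pooled_t(x, y)
    if scenario in ("t_neq", "t_neq_dagger"):
        return _welch_t(x, y)
    if scenario == "mw":
        return _mann_whitney(x, y)
    raise ScreenError(f"unknown scenario {scenario!r}")


def adaptive_p(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[str, float, float]:
    """One-shot (scenario, statistic, p) via the full decision tree."""
    scenario = _scenario(x, y, alpha, warn=False)
    stat, p = two_sample_p(x, y, scenario)
    return scenario, stat, p


def chi_square_independence(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ScreenError("contingency table must be 2-dimensional")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ScreenError("degenerate contingency table (zero row or column margin)")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if df == 0:
        return stat, 1.0
    return stat, float(special.chdtrc(df, stat))


# -- leave-k-out resampling robustness ----------------------------------------


def count_leave_k_out(n: int, depths: Iterable[int]) -> int:
    """Number of distinct participant subsets removable at the given depths."""
    return sum(math.comb(n, d) for d in depths)


def _leave_k_out_pvalues(
    pooled_p: Callable[[np.ndarray], float],
    n: int,
    depths: Sequence[int],
) -> list[float]:
    keep = np.ones(n, dtype=bool)
    out: list[float] = []
    for d in depths:
        for removed in combinations(range(n), d):
            keep[list(removed)] = False
            p = pooled_p(keep)
            if p is not None:
                out.append(p)
            keep[list(removed)] = True
    return out


def leave_k_out_fdr(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    depths: Sequence[int] = (1, 2),
    return_pvalues: bool = False,
):
    """Fraction of leave-k-out recomputed p-values failing the level.

    Every subset of 1..k participants (from the pooled cohort, either
    group) is removed in turn; the test-selection tree and the two-sample
    p-value are recomputed on what remains.  The returned score is the
    fraction of those p-values that EXCEED ``alpha`` -- 0 means the finding
    survives every deletion, 1 means it never reaches significance.

    Deletions that would leave a group below the minimum testable size are
    skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    depths = sorted(set(int(d) for d in depths))
    n1, n2 = x.size, y.size
    if any(d <= 0 for d in depths):
        raise ScreenError("leave-out depths must be positive")
    if max(depths) >= min(n1, n2):
        raise ScreenError("leave-out depth must be smaller than the smaller group")
    if n1 + n2 - max(depths) < 2 * MIN_SAMPLE:
        raise ScreenError("too few participants for the requested leave-out depths")
    pooled = np.concatenate([x, y])
    is_case = np.zeros(n1 + n2, dtype=bool)
    is_case[:n1] = True
    skipped = 0

    def pooled_p(keep: np.ndarray):
        nonlocal skipped
        xs = pooled[keep & is_case]
        ys = pooled[keep & ~is_case]
        if xs.size < MIN_SAMPLE or ys.size < MIN_SAMPLE:
            skipped += 1
            return None
        return adaptive_p(xs, ys, alpha)[2]

    pvalues = _leave_k_out_pvalues(pooled_p, n1 + n2, depths)
    if skipped:
        warnings.warn(f"{skipped} leave-out subset(s) skipped: a group fell below n={MIN_SAMPLE}")
    if not pvalues:
        raise ScreenError("no evaluable leave-out subsets")
    fdr = float(np.mean([p > alpha for p in pvalues]))
    return (fdr, pvalues) if return_pvalues else fdr


def _leave_k_out_fdr_binary(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    depths: Sequence[int],
) -> float:
    """Leave-k-out robustness for a chi-square feature (2 x k table)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    is_case = np.zeros(pooled.size, dtype=bool)
    is_case[:n1] = True
    levels = np.unique(pooled)

    def pooled_p(keep: np.ndarray):
        xs = pooled[keep & is_case]
        ys = pooled[keep & ~is_case]
        if xs.size < 2 or ys.size < 2:
            return None
        table = np.array(
            [[np.sum(s == lev) for lev in levels] for s in (xs, ys)], dtype=float
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            return 1.0
        return chi_square_independence(table)[1]

    pvalues = _leave_k_out_pvalues(pooled_p, pooled.size, sorted(set(depths)))
    if not pvalues:
        return 1.0
    return float(np.mean([p > alpha for p in pvalues]))


# -- ROC / AUC -----------------------------------------------------------------


def roc_auc(case: Sequence[float], control: Sequence[float]) -> float:
    """AUC via the Mann-Whitney identity, oriented so AUC >= 0.5.

    Equals the fraction of (case, control) pairs ordered concordantly, with
    half credit for ties.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ScreenError("AUC needs non-empty samples")
    ranks, _ = _rankdata(np.concatenate([x, y]))
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    a = u1 / (x.size * y.size)
    return float(max(a, 1.0 - a))


# -- full screen ---------------------------------------------------------------


def run_screen(
    m: CohortMatrix,
    alpha: float = 0.05,
    depths: Sequence[int] = (1, 2),
    fdr_threshold: float = 0.1,
    features: Sequence[str] | None = None,
) -> list[UnivariateResult]:
    """Screen every feature; results sorted by AUC descending.

    Continuous features go through the adaptive two-sample tree;
    binary/ordinal features are tested with chi-square on the group x level
    contingency table.  Significance is the joint rule
    ``p <= alpha and fdr <= fdr_threshold``.
    """
    names = list(features) if features is not None else m.feature_names
    results = []
    for name in names:
        meta = m.meta(name)
        case, control = m.feature_samples(name)
        if meta.kind == "continuous":
            if case.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0 and (
                case.mean() == control.mean()
            ):
                scenario, stat, p, fdr = "mw", float(case.size * control.size / 2), 1.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scenario, stat, p = adaptive_p(case, control, alpha)
                    fdr = leave_k_out_fdr(case, control, alpha=alpha, depths=depths)
            mean_case, sd_case = float(case.mean()), float(case.std(ddof=1))
            mean_control, sd_control = float(control.mean()), float(control.std(ddof=1))
        else:
            levels = np.unique(np.concatenate([case, control]))
            table = np.array(
                [[np.sum(s == lev) for lev in levels] for s in (case, control)], dtype=float
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p = chi_square_independence(table)
            scenario = "chi2"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fdr = _leave_k_out_fdr_binary(case, control, alpha, depths)
            mean_case = sd_case = mean_control = sd_control = math.nan
        auc = roc_auc(case, control)
        ratio = (
            float(case.mean() / control.mean())
            if meta.kind == "continuous" and control.mean() != 0
            else math.nan
        )
        results.append(
            UnivariateResult(
                feature=name,
                scenario=scenario,
                statistic=float(stat),
                p=float(p),
                fdr=float(fdr),
                auc=float(auc),
                mean_case=mean_case,
                sd_case=sd_case,
                mean_control=mean_control,
                sd_control=sd_control,
                ratio=ratio,
                significant=bool(p <= alpha and fdr <= fdr_threshold),
            )
        )
    results.sort(key=lambda r: (-r.auc, r.feature))
    return results


def screen_table(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Tabular export mirroring the univariate results-table layout."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test": [r.scenario for r in results],
            "mean_case": [r.mean_case for r in results],
            "sd_case": [r.sd_case for r in results],
            "mean_control": [r.mean_control for r in results],
            "sd_control": [r.sd_control for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "auc": [r.auc for r in results],
            "ratio": [r.ratio for r in results],
            "significant": [r.significant for r in results],
        }
    )
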