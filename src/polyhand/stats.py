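"""Behavioral analyses and the study's statistical conventions.

Group comparisons use two-sided Wilcoxon tests (rank-sum for independent
samples, signed-rank for paired samples) with exact p-values for small
tie-free samples, plus t-based 95% confidence intervals on the mean
difference. The reported convention throughout is six-fingered minus
five-fingered: positive differences mean larger values for the six-fingered
group, so the first sample passed to every two-sample routine is the
six-fingered one.

Learning curves from the video-game logs are ordinary least-squares fits of
level reached against cumulative practice time (hours); the two finger-use
conditions are compared by a bootstrap test that resamples each condition's
(time, level) events with replacement, refits the slopes, and reads a
two-sided p-value off the tail proportions of the slope-difference
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, DegenerateDataError, InsufficientDataError, ParameterError
from .recordings import GameSessionLog, LocalizationDataset

EXACT_N_CUTOFF = 12  # combined sample size up to which exact Wilcoxon p-values are used


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    ci: tuple[float, float] | None = None  # 95% CI on mean difference (six minus five)
    n_discarded: int = 0
    seed: int | None = None


@dataclass
class LearningCurve:
    condition: str
    slope: float  # levels per hour
    intercept: float
    n_events: int


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizationErrors:
    per_landmark: dict[tuple[str, str], float]  # mean error, cm
    per_finger: dict[str, float]
    overall: float


def localization_error(data: LocalizationDataset) -> LocalizationErrors:
    """Mean 2-D Euclidean distance between reported and true grid positions,
    per landmark, per finger, and overall."""
    per_landmark: dict[tuple[str, str], float] = {}
    finger_accum: dict[str, list[float]] = {}
    all_errors: list[float] = []
    for key, pairs in data.points.items():
        if not pairs:
            raise DataError(f"landmark {key} has no repetitions")
        errs = []
        for reported, true in pairs:
            reported = np.asarray(reported, dtype=float)
            true = np.asarray(true, dtype=float)
            if reported.shape != (2,) or true.shape != (2,):
                raise DataError(f"landmark {key}: points are not paired 2-D coordinates")
            errs.append(float(np.linalg.norm(reported - true)))
        per_landmark[key] = float(np.mean(errs))
        finger_accum.setdefault(key[0], []).extend(errs)
        all_errors.extend(errs)
    per_finger = {f: float(np.mean(v)) for f, v in finger_accum.items()}
    return LocalizationErrors(per_landmark=per_landmark, per_finger=per_finger,
                              overall=float(np.mean(all_errors)))


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

def _ols_slope(t_hours: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    t_mean = t_hours.mean()
    denom = float(np.sum((t_hours - t_mean) ** 2))
    if denom == 0:
        raise DegenerateDataError("all practice times equal; slope undefined")
    slope = float(np.sum((t_hours - t_mean) * (levels - levels.mean())) / denom)
    return slope, float(levels.mean() - slope * t_mean)


def learning_slope(log: GameSessionLog) -> LearningCurve:
    """OLS slope of level vs cumulative practice time, in levels per hour."""
    if len(log.events) < 3:
        raise InsufficientDataError(f"need >= 3 events, got {len(log.events)}")
    t_hours = log.times_min / 60.0
    slope, intercept = _ols_slope(t_hours, log.levels)
    return LearningCurve(condition=log.condition, slope=slope, intercept=intercept,
                         n_events=len(log.events))


def bootstrap_slope_diff(
    a: GameSessionLog,
    b: GameSessionLog,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Bootstrap comparison of two learning-curve slopes.

    Events are resampled with replacement within each condition; the slope
    difference a - b is refit per replicate; the two-sided p-value is
    2 * min(P(diff* <= 0), P(diff* >= 0)), floored at 1/n_boot. Replicates
    with a degenerate fit (all resampled times equal) are discarded and
    counted. Deterministic given ``seed``.
    """
    slope_a = learning_slope(a).slope
    slope_b = learning_slope(b).slope
    rng = np.random.default_rng(seed)

    def _boot_slopes(log: GameSessionLog) -> tuple[np.ndarray, np.ndarray]:
        t = log.times_min / 60.0
        y = log.levels
        n = len(t)
        idx = rng.integers(0, n, size=(n_boot, n))
        tb, yb = t[idx], y[idx]
        tc = tb - tb.mean(axis=1, keepdims=True)
        denom = np.sum(tc ** 2, axis=1)
        valid = denom > 0
        num = np.sum(tc * (yb - yb.mean(axis=1, keepdims=True)), axis=1)
        slopes = np.full(n_boot, np.nan)
        slopes[valid] = num[valid] / denom[valid]
        return slopes, valid

    sa, va = _boot_slopes(a)
    sb, vb = _boot_slopes(b)
    valid = va & vb
    n_discarded = int(n_boot - valid.sum())
    diffs = sa[valid] - sb[valid]
    if len(diffs) == 0:
        raise DegenerateDataError("all bootstrap replicates degenerate")
    p = 2.0 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0)))
    p = min(1.0, max(p, 1.0 / n_boot))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return TestResult(test="bootstrap_slope_diff", statistic=slope_a - slope_b,
                      p=p, ci=(float(lo), float(hi)), n_discarded=n_discarded,
                      seed=seed)


# ---------------------------------------------------------------------------
# Wilcoxon tests and t-intervals
# ---------------------------------------------------------------------------

def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_ranksum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    W is the sum of the ranks of ``x`` (by convention the six-fingered group)
    in the pooled midrank ranking. The p-value is exact (full enumeration of
    the rank-sum distribution) for combined n <= 12 without ties, otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    exact = len(pooled) <= EXACT_N_CUTOFF and not _has_ties(pooled)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    try:
        ci = mean_diff_ci(x, y, paired=False)
    except InsufficientDataError:
        ci = None
    return TestResult(test="wilcoxon_ranksum", statistic=w, p=float(res.pvalue), ci=ci)


def wilcoxon_signedrank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    W is the sum of the ranks of the positive differences x - y (zero
    differences dropped). Exact p for n <= 12 tie-free differences, normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 1:
        raise ParameterError("paired samples must have equal length >= 1")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(test="wilcoxon_signedrank", statistic=0.0, p=1.0,
                          ci=mean_diff_ci(x, y, paired=True) if len(x) >= 2 else None)
    ranks = sps.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    exact = len(nz) <= EXACT_N_CUTOFF
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                       alternative="two-sided",
                       method="exact" if exact else "approx")
    ci = mean_diff_ci(x, y, paired=True) if len(x) >= 2 else None
    return TestResult(test="wilcoxon_signedrank", statistic=w_pos,
                      p=float(res.pvalue), ci=ci)


def mean_diff_ci(x, y, paired: bool, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval on mean(x) - mean(y).

    Pooled-variance two-sample t-interval for independent samples, paired
    t-interval on the differences otherwise. With ``x`` the six-fingered
    group, positive values indicate larger six-fingered means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y) or len(x) < 2:
            raise InsufficientDataError("paired interval needs equal lengths >= 2")
        d = x - y
        n = len(d)
        se = float(np.std(d, ddof=1)) / np.sqrt(n)
        df = n - 1
        center = float(d.mean())
    else:
        if len(x) < 2 or len(y) < 2:
            raise InsufficientDataError("two-sample interval needs n >= 2 per group")
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        se = float(np.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))
        df = nx + ny - 2
        center = float(x.mean() - y.mean())
    if se == 0:
        warnings.warn("zero variance; degenerate interval", stacklevel=2)
        return (center, center)
    half = float(sps.t.ppf(0.5 + level / 2.0, df)) * se
    return (center - half, center + half)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need equal lengths >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("constant input; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
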