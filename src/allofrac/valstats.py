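"""Analytical-validation statistics for quantitative assays.

Implements the detection-capability and method-comparison machinery used to
validate clinical quantitative tests:

* limit of blank (LoB) by the nonparametric rank rule; limit of detection
  (LoD) by the parametric rule ``LoD = LoB + cp * SD_low`` with the
  small-sample multiplier ``cp = 1.645 / (1 - 1/(4(L - J)))``; limit of
  quantitation (LoQ) either from a precision profile (fitted %CV-vs-level
  curve crossing a target CV) or from a total-error bound
  ``TE = Bias + 2*SD``;
* polynomial linearity assessment (first- through third-order fits, with
  the highest-order coefficient's significance deciding each order);
* replicate precision summaries (%CV per group and pooled);
* Passing-Bablok regression — the nonparametric, shifted-median-of-pairwise-
  slopes method-comparison regression robust to error in both variables —
  with rank-based confidence intervals and the equivalence rule (slope CI
  containing 1 and intercept CI containing 0);
* empirical ROC analysis with Youden-index cutoff selection and
  sensitivity/specificity/NPV/PPV at the chosen cutoff;
* nonparametric reference intervals by rank interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DetectionLimits",
    "PbRegression",
    "RocSummary",
    "LinearityReport",
    "PrecisionSummary",
    "lob_nonparametric",
    "cp_multiplier",
    "lod_parametric",
    "loq_precision_profile",
    "loq_lowest_passing",
    "loq_total_error",
    "linearity_assess",
    "precision_summary",
    "passing_bablok",
    "roc_analysis",
    "reference_interval",
]


@dataclass(frozen=True)
class DetectionLimits:
    """LoB/LoD/LoQ triple with the inputs that produced it."""

    lob: float
    lod: float
    loq: float
    alpha: float = 0.05
    beta: float = 0.05
    n_blanks: Optional[int] = None
    L: Optional[int] = None
    J: Optional[int] = None
    cp: Optional[float] = None
    sd_low: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.lob <= self.lod <= self.loq:
            raise ValueError(
                f"detection limits must be ordered lob <= lod <= loq, got "
                f"{self.lob} / {self.lod} / {self.loq}"
            )


@dataclass(frozen=True)
class PbRegression:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    equivalent: bool

    def __post_init__(self) -> None:
        if not self.slope_ci[0] <= self.slope <= self.slope_ci[1]:
            raise ValueError("slope CI does not contain the point estimate")
        if not self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]:
            raise ValueError("intercept CI does not contain the point estimate")


@dataclass(frozen=True)
class RocSummary:
    auc: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    npv: float  # percent
    ppv: float  # percent
    youden_j: float  # percent scale: sens + spec - 100


@dataclass(frozen=True)
class LinearityReport:
    range_assessed: tuple[float, float]
    linear_p: float
    linear_r2: float
    second_order_p: float
    third_order_p: Optional[float]
    verdict: str  # "linear" | "nonlinear"


@dataclass(frozen=True)
class PrecisionSummary:
    groups: dict[str, dict[str, float]]  # name -> {mean, sd, cv_percent, n}
    pooled_mean: float
    pooled_sd: float
    pooled_cv_percent: float


# --------------------------------------------------------------------------
# Detection limits
# --------------------------------------------------------------------------

def lob_nonparametric(blanks: Sequence[float], alpha: float = 0.05) -> float:
    """Nonparametric limit of blank: the ``1 - alpha`` rank of sorted blanks.

    The rank position is ``0.5 + B * (1 - alpha)`` rounded half-up to an
    integer (so 757 blanks at alpha 0.05 give rank 720), and the LoB is the
    blank value at that rank. All-zero blanks (no amplification at all)
    yield LoB = 0.
    """
    b = np.sort(np.asarray(blanks, dtype=float))
    if b.size < 20:
        raise ValueError(f"LoB requires >= 20 blank measurements, got {b.size}")
    if np.all(b == 0):
        return 0.0
    rank = lob_rank_position(b.size, alpha)
    return float(b[min(rank, b.size) - 1])


def lob_rank_position(n_blanks: int, alpha: float = 0.05) -> int:
    """Integer rank position ``round_half_up(0.5 + B (1 - alpha))``."""
    raw = 0.5 + n_blanks * (1.0 - alpha)
    return int(math.floor(raw + 0.5))


def cp_multiplier(L: int, J: int) -> float:
    """Small-sample bias multiplier ``1.645 / (1 - 1/(4(L - J)))``.

    ``L`` is the total number of low-level measurements and ``J`` the number
    of distinct low-level samples; the multiplier decreases to its 1.645
    asymptote as ``L - J`` grows.
    """
    if J < 1 or L <= J:
        raise ValueError(f"require L > J >= 1, got L={L}, J={J}")
    return 1.645 / (1.0 - 1.0 / (4.0 * (L - J)))


def lod_parametric(
    lob: float,
    sd_low: float | Sequence[float],
    L: Optional[int] = None,
    J: Optional[int] = None,
    cp: Optional[float] = None,
    lobs: Optional[Sequence[float]] = None,
) -> float:
    """Parametric limit of detection, ``LoD = LoB + cp * SD_low``.

    Pass either the multiplier ``cp`` directly or ``L`` and ``J`` to compute
    it. ``sd_low`` may be a sequence of per-reagent-lot SDs (optionally with
    per-lot ``lobs``), in which case the greatest per-lot LoD is returned.
    """
    if cp is None:
        if L is None or J is None:
            raise ValueError("provide cp or both L and J")
        cp = cp_multiplier(L, J)
    sds = np.atleast_1d(np.asarray(sd_low, dtype=float))
    if np.any(sds < 0):
        raise ValueError("sd_low must be non-negative")
    lob_arr = (np.atleast_1d(np.asarray(lobs, dtype=float))
               if lobs is not None else np.full(sds.shape, lob))
    if lob_arr.shape != sds.shape:
        raise ValueError("lobs must match sd_low in length")
    return float(np.max(lob_arr + cp * sds))


def loq_precision_profile(
    levels: Sequence[tuple[float, Sequence[float]]],
    cv_target: float = 20.0,
    lod: float = 0.0,
) -> tuple[float, dict]:
    """Limit of quantitation from a precision profile.

    ``levels`` holds ``(level, per-sample %CVs)`` pairs. The mean %CV per
    level is fitted with a power law ``CV = a * level**b`` (a line on
    log-log axes); the LoQ is the level at which the fitted curve crosses
    ``cv_target``, floored at the LoD. If every mean CV is already below the
    target (a flat profile), the lowest level is returned with a flag.
    Returns ``(loq, info)`` where info holds the fit and the per-level means.
    """
    if len(levels) < 3:
        raise ValueError("precision profile requires >= 3 levels")
    lv = np.array([float(l) for l, _ in levels])
    if np.any(lv <= 0):
        raise ValueError("levels must be positive")
    mean_cv = np.array([float(np.mean(np.asarray(cvs, dtype=float)))
                        for _, cvs in levels])
    info: dict = {"levels": lv, "mean_cv": mean_cv, "flat_profile": False}

    b, log_a = np.polyfit(np.log(lv), np.log(mean_cv), 1)
    info["fit"] = {"a": float(np.exp(log_a)), "b": float(b)}
    if np.all(mean_cv < cv_target):
        info["flat_profile"] = True
        loq = float(lv.min())
    elif b >= 0:
        # CV not decreasing with level: cannot invert, report highest level
        info["flat_profile"] = True
        loq = float(lv.max())
    else:
        # a * level**b = cv_target  =>  level = (cv_target / a)**(1/b)
        loq = float((cv_target / np.exp(log_a)) ** (1.0 / b))
    return max(loq, lod), info


def loq_lowest_passing(
    levels: Sequence[tuple[float, float]], cv_limit: float = 30.0
) -> float:
    """LoQ as the lowest measured level whose %CV is confirmed below the limit.

    ``levels`` holds ``(measured mean, %CV)`` pairs; used when the precision
    profile is flat and the predicted crossing falls below the blank range.
    """
    passing = [(mean, cv) for mean, cv in levels if cv < cv_limit]
    if not passing:
        raise ValueError(f"no level passes %CV < {cv_limit}")
    return float(min(mean for mean, _ in passing))


def loq_total_error(
    measured_mean: float, measured_sd: float, assigned_value: float
) -> dict[str, float]:
    """Total-error LoQ statistics: ``bias = mean - assigned``, ``TE = bias + 2 SD``.

    Returns absolute bias and TE plus TE relative to the assigned value.
    """
    if assigned_value <= 0:
        raise ValueError("assigned_value must be positive")
    bias = measured_mean - assigned_value
    te = bias + 2.0 * measured_sd
    return {"bias": float(bias), "te": float(te),
            "te_relative": float(te / assigned_value)}


# --------------------------------------------------------------------------
# Linearity and precision
# --------------------------------------------------------------------------

def linearity_assess(
    expected: Sequence[float],
    measured: Sequence[float],
    max_order: int = 3,
    alpha: float = 0.05,
) -> LinearityReport:
    """Polynomial linearity assessment.

    Fits ordinary least squares polynomials of order 1..max_order in the
    expected level and tests the significance of the highest-order
    coefficient of each. The verdict is linear when the first-order fit is
    significant and no higher order adds a significant term.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expected and measured must have equal length")
    n_levels = np.unique(x).size
    if n_levels < max_order + 2:
        raise ValueError(
            f"need >= {max_order + 2} distinct expected levels for order "
            f"{max_order}, got {n_levels}"
        )

    pvals: dict[int, float] = {}
    r2_1 = 0.0
    for order in range(1, max_order + 1):
        X = sm.add_constant(np.vander(x, order + 1, increasing=True)[:, 1:])
        fit = sm.OLS(y, X).fit()
        pvals[order] = float(fit.pvalues[-1])
        if order == 1:
            r2_1 = float(fit.rsquared)
    verdict = "linear" if (
        pvals[1] < alpha and all(pvals[o] >= alpha for o in range(2, max_order + 1))
    ) else "nonlinear"
    return LinearityReport(
        range_assessed=(float(x.min()), float(x.max())),
        linear_p=pvals[1], linear_r2=r2_1,
        second_order_p=pvals.get(2, float("nan")),
        third_order_p=pvals.get(3),
        verdict=verdict,
    )


def precision_summary(groups: dict[str, Sequence[float]]) -> PrecisionSummary:
    """Per-group and pooled mean / SD / %CV of replicate measurements."""
    out: dict[str, dict[str, float]] = {}
    all_values: list[float] = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r}: >= 2 replicates required")
        mean = float(v.mean())
        if mean == 0:
            raise ValueError(f"group {name!r}: zero mean, %CV undefined")
        sd = float(v.std(ddof=1))
        out[name] = {"mean": mean, "sd": sd,
                     "cv_percent": 100.0 * sd / mean, "n": int(v.size)}
        all_values.extend(v.tolist())
    pooled = np.asarray(all_values)
    pm = float(pooled.mean())
    ps = float(pooled.std(ddof=1))
    return PrecisionSummary(groups=out, pooled_mean=pm, pooled_sd=ps,
                            pooled_cv_percent=100.0 * ps / pm if pm else float("inf"))


# --------------------------------------------------------------------------
# Passing-Bablok method comparison
# --------------------------------------------------------------------------

def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """All valid pairwise slopes and the offset K (count of slopes < -1).

    Identical points contribute nothing; vertical pairs contribute +/-inf
    with the sign of the y-difference; slopes of exactly -1 are discarded,
    per the standard procedure.
    """
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    both_zero = (dx == 0) & (dy == 0)
    dx, dy = dx[~both_zero], dy[~both_zero]
    with np.errstate(divide="ignore"):
        s = np.where(dx == 0, np.sign(dy) * np.inf, dy / np.where(dx == 0, 1, dx))
    s = s[s != -1.0]
    K = int(np.sum(s < -1.0))
    return np.sort(s), K


def passing_bablok(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> PbRegression:
    """Passing-Bablok regression of y on x with rank-based confidence intervals.

    The slope is the shifted median of all pairwise slopes (shifted by the
    count K of slopes below -1, making the estimate invariant to swapping
    axes); the intercept is ``median(y - slope * x)``. Confidence bounds use
    the normal approximation of the rank statistic; ``equivalent`` is true
    when the slope CI contains 1 and the intercept CI contains 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError(f"Passing-Bablok requires >= 10 pairs, got {n}")
    if np.all(x == x[0]):
        raise ValueError("all x values identical")

    s, K = _pairwise_slopes(x, y)
    N = s.size
    if N == 0:
        raise ValueError("no valid pairwise slopes")

    def shifted_median(offset: int) -> float:
        if N % 2:
            return float(s[(N + 1) // 2 + offset - 1])
        lo = s[N // 2 + offset - 1]
        hi = s[N // 2 + offset]
        if np.isinf(lo) and np.isinf(hi):
            return float(lo)
        return float(0.5 * (lo + hi))

    slope = shifted_median(K)

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    c_gamma = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - c_gamma) / 2.0))
    m2 = N - m1 + 1
    lo_idx = max(m1 + K, 1)
    hi_idx = min(m2 + K, N)
    slope_lo = float(s[lo_idx - 1])
    slope_hi = float(s[hi_idx - 1])

    intercept = float(np.median(y - slope * x))
    # intercept bounds come from the opposite slope bounds
    int_lo = float(np.median(y - slope_hi * x)) if np.isfinite(slope_hi) else -math.inf
    int_hi = float(np.median(y - slope_lo * x)) if np.isfinite(slope_lo) else math.inf
    if int_lo > int_hi:
        int_lo, int_hi = int_hi, int_lo

    equivalent = (slope_lo <= 1.0 <= slope_hi) and (int_lo <= 0.0 <= int_hi)
    return PbRegression(
        slope=slope, intercept=intercept,
        slope_ci=(slope_lo, slope_hi), intercept_ci=(int_lo, int_hi),
        n=n, equivalent=equivalent,
    )


# --------------------------------------------------------------------------
# ROC / Youden
# --------------------------------------------------------------------------

def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocSummary:
    """Empirical ROC with Youden-index cutoff selection.

    Positivity is ``score >= cutoff``. The AUC uses the rank (Mann-Whitney)
    formulation with tie correction. Candidate cutoffs are the midpoints
    between adjacent distinct scores plus the extremes; Youden-J ties break
    toward the higher cutoff (higher specificity, conserving the negative
    predictive value).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    distinct = np.unique(scores)
    candidates = np.concatenate((
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ))
    best = None
    for c in candidates:
        pred = scores >= c
        tp = int(np.sum(pred & (labels == 1)))
        fn = n1 - tp
        fp = int(np.sum(pred & (labels == 0)))
        tn = n0 - fp
        sens = 100.0 * tp / n1
        spec = 100.0 * tn / n0
        j = sens + spec - 100.0
        # ties break toward the higher cutoff (>= keeps updating on ties as
        # candidates ascend)
        if best is None or j >= best[0] - 1e-12:
            npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
            ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
            best = (j, float(c), sens, spec, npv, ppv)
    j, cutoff, sens, spec, npv, ppv = best
    return RocSummary(auc=float(auc), cutoff=cutoff, sensitivity=sens,
                      specificity=spec, npv=npv, ppv=ppv, youden_j=j)


# --------------------------------------------------------------------------
# Reference intervals
# --------------------------------------------------------------------------

def reference_interval(
    values: Sequence[float],
    coverage: float = 0.95,
    subject_ids: Optional[Sequence] = None,
) -> tuple[float, float]:
    """Nonparametric central reference interval by rank interpolation.

    Bounds sit at percentiles ``(1 - coverage)/2`` and ``1 - (1 -
    coverage)/2`` using rank position ``r = p * (n + 1)`` with linear
    interpolation between order statistics (clipped to the observed range).
    When ``subject_ids`` are supplied, values are first averaged per subject
    so repeat measurements do not dominate.
    """
    v = np.asarray(values, dtype=float)
    if subject_ids is not None:
        import pandas as pd

        v = pd.Series(v).groupby(list(subject_ids)).mean().to_numpy()
    if v.size < 2:
        raise ValueError("reference interval requires >= 2 values")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if v.size < 40:
        warnings.warn(
            f"only {v.size} values; nonparametric reference limits are "
            "recommended for n >= 40", stacklevel=2,
        )
    v = np.sort(v)
    n = v.size

    def at_rank(p: float) -> float:
        r = p * (n + 1)
        if r <= 1:
            return float(v[0])
        if r >= n:
            return float(v[-1])
        lo = int(math.floor(r))
        frac = r - lo
        return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))

    tail = (1.0 - coverage) / 2.0
    return at_rank(tail), at_rank(1.0 - tail)
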