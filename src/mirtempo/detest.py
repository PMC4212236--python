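"""Per-feature differential-expression testing of NQT profiles.

The testing cascade runs in two stages:

1. **Linear stage** (needs >= 3 time points): ordinary least squares of a
   feature's NQT values on the time design 1..T, with the regression
   F-test on (1, T-2) degrees of freedom.  Features with p < alpha are
   classified ``linear_significant``.

2. **Non-linear stage** on the remainder:

   * T <= 3 — a normal-CDF test of the NQT shift between time point 1 and
     each later time point: p = Phi(tp_n - tp_1).  The test is one-sided
     as printed in the original formulation (small p for decreases); a
     two-sided variant p = 2 (1 - Phi(|d|)) is available via config.
   * T > 3 — Welch's unequal-variances one-way ANOVA between two pooled
     groups of time points: early = {1..floor(T/2)}, late = the rest.

With only two time points a linear fit is saturated (zero residual
degrees of freedom), so the linear stage is skipped and every feature
goes to the CDF test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InvalidDfError,
    TooFewTimePointsError,
    ZeroWithinGroupVarianceError,
)
from .matrix_io import AnalysisConfig
from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """OLS fit of one feature's NQT profile on the time design."""

    p_value: float
    intercept: float
    slope: float
    f_statistic: float
    df_num: int
    df_den: int
    design_times: np.ndarray
    perfect_fit: bool = False  # residual SS == 0; p reported as 0

    #: p-value after optional multiple-testing adjustment (set by the runner)
    p_adjusted: float | None = None

    def effective_p(self) -> float:
        return self.p_adjusted if self.p_adjusted is not None else self.p_value


@dataclass
class NonlinearResult:
    """CDF or Welch-ANOVA result for one feature."""

    method: str  # "CDF" or "ANOVA"
    cdf_pvals: dict[str, float] = field(default_factory=dict)
    anova_pval: float | None = None
    group_assignment: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    flag: str | None = None
    p_adjusted: float | None = None

    def min_p_value(self) -> float:
        if self.method == "CDF":
            return min(self.cdf_pvals.values())
        return self.anova_pval

    def effective_p(self) -> float:
        return self.p_adjusted if self.p_adjusted is not None else self.min_p_value()


@dataclass
class FeatureTestResult:
    """Final per-feature outcome of the testing cascade."""

    feature_name: str
    linear: LinearFit | None
    nonlinear: NonlinearResult | None
    classification: str  # linear_significant | nonlinear_significant | not_significant
    alpha_used: float
    reason: str | None = None


def fit_linear(y: np.ndarray, x: np.ndarray) -> LinearFit:
    """Ordinary least squares of y on x with the regression F-test.

    slope = Sxy/Sxx, intercept = ybar - slope * xbar,
    F = SS_regression / (SS_residual / (T - 2)) on (1, T-2) df.

    A perfect fit (zero residual sum of squares) reports p = 0 with the
    ``perfect_fit`` flag; a constant y gives F = 0 and p = 1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    T = y.size
    if x.size != T or T < 3:
        raise DegenerateDesignError(
            f"need >= 3 equal-length design points, got len(y)={T}, len(x)={x.size}"
        )
    if np.any(np.diff(x) <= 0):
        raise DegenerateDesignError("design times must be strictly increasing")

    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_reg = slope * sxy  # = sxy^2 / sxx
    ss_tot = float(np.sum((y - ybar) ** 2))
    ss_res = max(ss_tot - ss_reg, 0.0)
    df_den = T - 2

    # relative tolerance: residual indistinguishable from zero at double precision
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        if ss_reg == 0.0:  # y constant: no trend at all
            return LinearFit(1.0, intercept, slope, 0.0, 1, df_den, x)
        return LinearFit(0.0, intercept, slope, float("inf"), 1, df_den, x,
                         perfect_fit=True)
    f_stat = ss_reg / (ss_res / df_den)
    p = f_pvalue(f_stat, 1, df_den)
    return LinearFit(p, intercept, slope, f_stat, 1, df_den, x)


def f_pvalue(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution at *f*."""
    if df1 < 1 or df2 < 1:
        raise InvalidDfError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    return float(stats.f.sf(f, df1, df2))


def cdf_test(tp1: float, tpn: float, two_sided: bool = False) -> float:
    """Normal-CDF p-value for the NQT shift between time point 1 and n.

    One-sided (default): p = Phi(tpn - tp1), small when expression drops.
    Two-sided: p = 2 (1 - Phi(|tpn - tp1|)).
    """
    d = float(tpn) - float(tp1)
    if not np.isfinite(d):
        raise ValueError("cdf_test requires finite NQT values")
    if two_sided:
        return float(2.0 * stats.norm.sf(abs(d)))
    return float(stats.norm.cdf(d))


def assign_anova_groups(T: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Deterministic half split of time points 1..T into early/late groups.

    early = {1..floor(T/2)}, late = {floor(T/2)+1..T}; requires T >= 4 so
    each group has at least two members.
    """
    if T < 4:
        raise TooFewTimePointsError(f"ANOVA grouping needs T >= 4, got {T}")
    half = T // 2
    return tuple(range(1, half + 1)), tuple(range(half + 1, T + 1))


def welch_anova(
    y: np.ndarray, groups: tuple[tuple[int, ...], tuple[int, ...]]
) -> float:
    """Welch's unequal-variances one-way ANOVA p-value.

    *y* holds one value per time point (1-based indices in *groups*).
    Uses the general k-group Welch statistic with weights w_i = n_i/s_i^2
    and the Welch-Satterthwaite denominator degrees of freedom.

    Zero within-group variance makes the weights undefined; following the
    documented convention the p-value degenerates to 0 when the group
    means differ and 1 when they are equal, with a logged decision.
    """
    y = np.asarray(y, dtype=float)
    samples = [y[np.asarray(g, dtype=int) - 1] for g in groups]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("welch_anova needs >= 2 groups with >= 2 members each")

    ns = np.array([s.size for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    variances = np.array([s.var(ddof=1) for s in samples])
    if np.any(variances == 0):
        equal = np.allclose(means, means[0])
        logger.info(
            "welch_anova: zero within-group variance; reporting p=%d by convention",
            1 if equal else 0,
        )
        return 1.0 if equal else 0.0

    k = len(samples)
    w = ns / variances
    grand = float(np.sum(w * means) / np.sum(w))
    a = float(np.sum(w * (means - grand) ** 2) / (k - 1))
    lam = float(np.sum((1.0 - w / np.sum(w)) ** 2 / (ns - 1.0)))
    b = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    f_stat = a / b
    df2 = (k**2 - 1.0) / (3.0 * lam)
    return float(stats.f.sf(f_stat, k - 1, df2))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    if pvals.size == 0:
        return pvals
    return stats.false_discovery_control(pvals, method="bh")


def run_de_analysis(
    nm: NormalizedMatrix,
    config: AnalysisConfig,
    design_times: np.ndarray | None = None,
) -> list[FeatureTestResult]:
    """Run the full testing cascade over every feature of *nm*.

    Returns one :class:`FeatureTestResult` per feature, in input order.
    Per-feature failures are contained: the feature is labeled
    ``not_significant`` with a reason instead of aborting the run.
    Optional Benjamini-Hochberg adjustment is applied within each test
    family (linear; each CDF comparison; ANOVA) before classification.
    """
    T = nm.n_timepoints
    alpha = config.alpha
    x = (
        np.asarray(design_times, dtype=float)
        if design_times is not None
        else np.arange(1, T + 1, dtype=float)
    )
    if x.size != T:
        raise DegenerateDesignError(
            f"design_times has {x.size} entries for {T} time points"
        )
    adjust = config.multiple_testing == "benjamini_hochberg"

    results: list[FeatureTestResult] = []
    # --- linear stage ---
    linear_fits: list[LinearFit | None] = []
    for i, name in enumerate(nm.feature_names):
        if T < 3:
            linear_fits.append(None)
            continue
        try:
            linear_fits.append(fit_linear(nm.nqt[i], x))
        except DegenerateDesignError as exc:
            logger.warning("feature %s: linear fit failed (%s)", name, exc)
            linear_fits.append(None)

    if adjust and T >= 3:
        fitted = [f for f in linear_fits if f is not None]
        adjusted = _bh_adjust(np.array([f.p_value for f in fitted]))
        for f, p_adj in zip(fitted, adjusted):
            f.p_adjusted = float(p_adj)

    linear_sig = [
        f is not None and f.effective_p() < alpha for f in linear_fits
    ]

    # --- non-linear stage on the remainder ---
    remainder = [i for i in range(nm.n_features) if not linear_sig[i]]
    nonlinear: dict[int, NonlinearResult] = {}
    failures: dict[int, str] = {}
    if T <= 3:
        comparisons = [(1, t) for t in range(2, T + 1)]
        for i in remainder:
            pvals = {
                f"tp1_vs_tp{tn}": cdf_test(
                    nm.nqt[i, 0], nm.nqt[i, tn - 1], two_sided=config.cdf_two_sided
                )
                for (_, tn) in comparisons
            }
            nonlinear[i] = NonlinearResult(method="CDF", cdf_pvals=pvals)
        if adjust:
            for _, tn in comparisons:
                key = f"tp1_vs_tp{tn}"
                idx = list(nonlinear)
                adj = _bh_adjust(np.array([nonlinear[i].cdf_pvals[key] for i in idx]))
                for i, p_adj in zip(idx, adj):
                    nonlinear[i].cdf_pvals[key + "_adj"] = float(p_adj)
            for res in nonlinear.values():
                res.p_adjusted = min(
                    v for k, v in res.cdf_pvals.items() if k.endswith("_adj")
                )
    else:
        groups = assign_anova_groups(T)
        for i in remainder:
            try:
                p = welch_anova(nm.nqt[i], groups)
            except (ZeroWithinGroupVarianceError, ValueError) as exc:
                logger.warning(
                    "feature %s: ANOVA failed (%s)", nm.feature_names[i], exc
                )
                failures[i] = str(exc)
                continue
            flag = None
            if any(
                np.var(nm.nqt[i, np.asarray(g, dtype=int) - 1], ddof=1) == 0
                for g in groups
            ):
                flag = "zero_within_group_variance"
            nonlinear[i] = NonlinearResult(
                method="ANOVA", anova_pval=p, group_assignment=groups, flag=flag
            )
        if adjust:
            idx = list(nonlinear)
            adj = _bh_adjust(np.array([nonlinear[i].anova_pval for i in idx]))
            for i, p_adj in zip(idx, adj):
                nonlinear[i].p_adjusted = float(p_adj)

    # --- classification ---
    for i, name in enumerate(nm.feature_names):
        if linear_sig[i]:
            results.append(
                FeatureTestResult(name, linear_fits[i], None,
                                  "linear_significant", alpha)
            )
        elif i in nonlinear:
            res = nonlinear[i]
            sig = res.effective_p() < alpha
            results.append(
                FeatureTestResult(
                    name, linear_fits[i], res,
                    "nonlinear_significant" if sig else "not_significant", alpha,
                )
            )
        else:
            results.append(
                FeatureTestResult(
                    name, linear_fits[i], None, "not_significant", alpha,
                    reason=failures.get(i, "no applicable test"),
                )
            )
    return results
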