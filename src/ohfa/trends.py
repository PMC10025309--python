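"""Per-strain trend statistics: OLS regressions, Spearman correlations,
one-way ANOVA with Tukey HSD post-hoc, and calibration inversion.

Regressions are fit on replicate-level points (e.g. 5 levels x 3 replicates
= 15 points) rather than level means; a flag switches to level means.
Significance is judged two-sided at alpha = 0.05 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import INDEX_NAMES, compute_indices
from .profiles import ExperimentSeries, aggregate_replicates

__all__ = [
    "TrendFit",
    "SpearmanResult",
    "AnovaTukeyResult",
    "ConstantConditionError",
    "NonSignificantFitError",
    "fit_linear_trend",
    "spearman",
    "anova_tukey",
    "trend_report",
    "invert_calibration",
]

ALPHA = 0.05


class ConstantConditionError(ValueError):
    """All condition values identical; a slope cannot be estimated."""


class NonSignificantFitError(ValueError):
    """Refusing to invert a calibration whose slope is not significant."""


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares fit of one response against the condition."""

    response_id: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    slope_se: float
    intercept_se: float
    slope_intercept_cov: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class SpearmanResult:
    rho: float | None
    p_value: float | None


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float | None
    p_value: float | None
    comparisons: pd.DataFrame
    degenerate: bool = False


def fit_linear_trend(
    x: Sequence[float], y: Sequence[float], response_id: str = "response"
) -> TrendFit:
    """OLS of ``y`` on ``x`` with the two-sided slope t-test (n-2 df).

    A constant ``y`` yields slope 0, R^2 = 0, p = 1. A constant ``x``
    raises :class:`ConstantConditionError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError("regression requires >= 3 points")
    if np.ptp(x) == 0:
        raise ConstantConditionError("all condition values are identical")

    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if np.ptp(y) == 0:
        # no variance to explain: flat fit by convention
        return TrendFit(
            response_id=response_id,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_value=1.0,
            n_points=n,
            slope_se=0.0,
            intercept_se=0.0,
            slope_intercept_cov=0.0,
        )

    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    s2 = float(np.sum(resid**2)) / (n - 2)
    var_slope = s2 / sxx
    var_intercept = s2 * (1.0 / n + xbar**2 / sxx)
    cov = -xbar * s2 / sxx
    return TrendFit(
        response_id=response_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_points=n,
        slope_se=math.sqrt(var_slope),
        intercept_se=math.sqrt(var_intercept),
        slope_intercept_cov=cov,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Constant input has no defined rank correlation; rho and p come back
    as ``None`` (reported as missing downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("spearman requires >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=None, p_value=None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return SpearmanResult(rho=None, p_value=None)
    return SpearmanResult(rho=float(rho), p_value=float(p))


def anova_tukey(
    groups: Mapping[float, Sequence[float]], alpha: float = ALPHA
) -> AnovaTukeyResult:
    """One-way ANOVA across condition levels plus Tukey HSD pairwise tests.

    ``groups`` maps each level to its response values. With zero
    within-group variance everywhere the result is flagged degenerate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    levels = sorted(groups)
    if len(levels) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrays = [np.asarray(groups[lv], dtype=float) for lv in levels]
    for lv, arr in zip(levels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lv} has < 2 values")
    pooled_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if pooled_within == 0:
        return AnovaTukeyResult(
            f_statistic=None,
            p_value=None,
            comparisons=pd.DataFrame(
                columns=["level_a", "level_b", "mean_difference", "p_adjusted", "significant"]
            ),
            degenerate=True,
        )
    f_stat, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "mean_difference": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        comparisons=pd.DataFrame(rows),
    )


def _response_values(series: ExperimentSeries) -> pd.DataFrame:
    """Replicate-level long frame: one row per profile per response."""
    rows = []
    universe = series.descriptor_universe()
    for profile in series.profiles:
        iset = compute_indices(profile)
        idx = iset.as_dict()
        for desc in universe:
            rows.append(
                {
                    "condition_value": profile.condition_value,
                    "replicate_id": profile.replicate_id,
                    "response": desc.label,
                    "value": profile.value_for(desc),
                }
            )
        for name, val in (
            ("total_iso", iset.iso),
            ("total_anteiso", iset.anteiso),
            ("total_normal", iset.normal),
        ):
            rows.append(
                {
                    "condition_value": profile.condition_value,
                    "replicate_id": profile.replicate_id,
                    "response": name,
                    "value": val,
                }
            )
        for name in INDEX_NAMES:
            rows.append(
                {
                    "condition_value": profile.condition_value,
                    "replicate_id": profile.replicate_id,
                    "response": name,
                    "value": idx[name],
                }
            )
    return pd.DataFrame(rows)


def trend_report(
    series: ExperimentSeries,
    responses: Sequence[str] | None = None,
    *,
    use_level_means: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One OLS :class:`TrendFit` per response against the series condition.

    Responses are every fatty-acid relative abundance, the three class
    totals and every index. Responses undefined in more than half the
    replicates are skipped with a warning. Columns: ``response, slope,
    intercept, r2, p, n, significant``.
    """
    long = _response_values(series)
    if responses is not None:
        long = long[long["response"].isin(set(responses))]
    n_profiles = len(series.profiles)
    out = []
    for response, grp in long.groupby("response", sort=False):
        grp = grp.dropna(subset=["value"])
        if len(grp) < max(3, (n_profiles + 1) // 2):
            warnings.warn(
                f"response {response!r} defined in {len(grp)}/{n_profiles} "
                "replicates; skipped",
                stacklevel=2,
            )
            continue
        if use_level_means:
            grp = (
                grp.groupby("condition_value", as_index=False)["value"].mean()
            )
        x = grp["condition_value"].to_numpy()
        y = grp["value"].to_numpy()
        if np.ptp(x) == 0 or len(x) < 3:
            continue
        fit = fit_linear_trend(x, y, response_id=response)
        out.append(
            {
                "response": response,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r_squared,
                "p": fit.p_value,
                "n": fit.n_points,
                "significant": fit.p_value < alpha,
            }
        )
    return pd.DataFrame(out)


def invert_calibration(
    fit: TrendFit, y0: float, *, alpha: float = ALPHA
) -> tuple[float, tuple[float, float]]:
    """Invert a fitted calibration line at ``y0``.

    Returns ``x_hat = (y0 - intercept) / slope`` and a first-order
    (delta-method) confidence interval propagating the slope/intercept
    covariance. Refuses non-significant fits.
    """
    if fit.slope == 0:
        raise NonSignificantFitError("cannot invert a flat calibration (slope 0)")
    if fit.p_value >= alpha:
        raise NonSignificantFitError(
            f"calibration slope not significant (p = {fit.p_value:.3g} >= {alpha}); "
            "refusing inverse prediction"
        )
    x_hat = (y0 - fit.intercept) / fit.slope
    # d x_hat / d intercept = -1/slope ; d x_hat / d slope = -x_hat/slope
    var = (
        fit.intercept_se**2
        + 2 * x_hat * fit.slope_intercept_cov
        + x_hat**2 * fit.slope_se**2
    ) / fit.slope**2
    var = max(var, 0.0)
    t_crit = stats.t.ppf(1 - alpha / 2, df=fit.n_points - 2)
    half = t_crit * math.sqrt(var)
    return x_hat, (x_hat - half, x_hat + half)
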