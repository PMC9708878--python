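"""Publication-bias diagnostics: Egger regression, Begg rank correlation, funnel data.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1 / SE) by ordinary least squares; a non-zero intercept indicates
small-study asymmetry.  Begg's test rank-correlates the standardized
deviates of the effects from the fixed-effect mean with their variances
(Kendall tau-b, continuity-corrected normal approximation).  Both need at
least three studies.  ``funnel_data`` emits the plot-ready scatter and the
pseudo-95% funnel boundary around a pooled estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .errors import InsufficientStudiesError
from .models import EffectEstimate, Z_95
from .pooling import PooledResult


@dataclass(frozen=True)
class BiasResult:
    """Outcome of one publication-bias test."""

    method: str  # "egger" or "begg"
    statistic: float  # Egger: intercept t; Begg: continuity-corrected z
    p: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    slope: float | None = None
    tau_kendall: float | None = None


def egger_test(effects: list[EffectEstimate]) -> BiasResult:
    """Egger's linear regression test for funnel asymmetry.

    OLS of y_i/se_i on 1/se_i; the intercept's t statistic is referred to
    Student's t with k-2 df (two-sided).
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    x = np.array([1.0 / e.se for e in effects])
    y = np.array([e.log_or / e.se for e in effects])
    x_bar, y_bar = x.mean(), y.mean()
    sxx = np.sum((x - x_bar) ** 2)
    if sxx == 0:
        raise InsufficientStudiesError("all standard errors identical; slope undefined")
    slope = float(np.sum((x - x_bar) * (y - y_bar)) / sxx)
    intercept = float(y_bar - slope * x_bar)
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (k - 2))
    se_int = math.sqrt(s2 * (1.0 / k + x_bar**2 / sxx))
    t_stat = intercept / se_int
    p = float(2.0 * t_dist.sf(abs(t_stat), k - 2))
    return BiasResult(
        method="egger", statistic=t_stat, p=p, k=k,
        intercept=intercept, intercept_se=se_int, slope=slope,
    )


def _kendall_s_var(u: np.ndarray, v: np.ndarray) -> tuple[int, float, float]:
    """Kendall score S, its null variance (tie-corrected), and tau-b."""
    n = len(u)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign((u[i + 1:] - u[i]) * (v[i + 1:] - v[i]))))

    def tie_sizes(x: np.ndarray) -> np.ndarray:
        _, counts = np.unique(x, return_counts=True)
        return counts[counts > 1].astype(float)

    t_ties, u_ties = tie_sizes(u), tie_sizes(v)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(t_ties * (t_ties - 1) * (2 * t_ties + 5)))
    vu = float(np.sum(u_ties * (u_ties - 1) * (2 * u_ties + 5)))
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        v1 = (
            float(np.sum(t_ties * (t_ties - 1)))
            * float(np.sum(u_ties * (u_ties - 1)))
            / (2.0 * n * (n - 1))
        )
        v2 = (
            float(np.sum(t_ties * (t_ties - 1) * (t_ties - 2)))
            * float(np.sum(u_ties * (u_ties - 1) * (u_ties - 2)))
            / (9.0 * n * (n - 1) * (n - 2))
        )
        var += v1 + v2
    n0 = n * (n - 1) / 2.0
    t1 = float(np.sum(t_ties * (t_ties - 1) / 2.0))
    t2 = float(np.sum(u_ties * (u_ties - 1) / 2.0))
    denom = math.sqrt((n0 - t1) * (n0 - t2))
    tau_b = s / denom if denom > 0 else 0.0
    return s, var, tau_b


def begg_test(effects: list[EffectEstimate]) -> BiasResult:
    """Begg-Mazumdar rank correlation test for funnel asymmetry.

    Standardized deviates v_i = (y_i - y_FE) / sqrt(var_i - var_pooled) are
    rank-correlated with the variances; the Kendall score is normalized with
    tie-corrected variance and a continuity correction.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs k >= 3, got {k}")
    var = np.array([e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    w = 1.0 / var
    y_fe = float(np.sum(w * y) / np.sum(w))
    var_pool = 1.0 / float(np.sum(w))
    dev = (y - y_fe) / np.sqrt(np.maximum(var - var_pool, 1e-12))
    s, var_s, tau_b = _kendall_s_var(dev, var)
    if var_s <= 0:
        z = 0.0
    else:
        z = (abs(s) - 1) / math.sqrt(var_s) if s != 0 else 0.0
        z = max(z, 0.0)
    p = float(2.0 * norm.sf(z))
    return BiasResult(
        method="begg", statistic=z, p=min(p, 1.0), k=k, tau_kendall=tau_b
    )


@dataclass(frozen=True)
class FunnelData:
    """Plot-ready funnel scatter and pseudo-confidence boundary."""

    points: pd.DataFrame  # study_id, or_, log_or, se
    boundary: pd.DataFrame  # se, or_low, or_high (around the pooled estimate)


def funnel_data(
    effects: list[EffectEstimate], pooled: PooledResult, n_boundary: int = 50
) -> FunnelData:
    """Funnel-plot coordinates: per-study points and the pseudo-95% funnel."""
    if not effects:
        raise InsufficientStudiesError("funnel data needs at least one effect")
    points = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "or_": [e.or_ for e in effects],
            "log_or": [e.log_or for e in effects],
            "se": [e.se for e in effects],
        }
    )
    se_max = max(e.se for e in effects)
    se_grid = np.linspace(0.0, se_max * 1.05, n_boundary)
    boundary = pd.DataFrame(
        {
            "se": se_grid,
            "or_low": np.exp(pooled.log_or - Z_95 * se_grid),
            "or_high": np.exp(pooled.log_or + Z_95 * se_grid),
        }
    )
    return FunnelData(points=points, boundary=boundary)
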