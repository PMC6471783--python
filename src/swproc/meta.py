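"""Random-effects meta-analysis and meta-regression of site-level effects.

Site effects (log odds ratios or log proportion ratios with standard
errors) are pooled with the DerSimonian-Laird (DL) method-of-moments
between-site variance estimator, and regressed on site-level covariates
(e.g. implementation-strength scores) by method-of-moments
meta-regression: the residual heterogeneity tau^2 is estimated from the
weighted residual Q-statistic of a fixed-effect weighted least squares
fit, then the coefficients are re-estimated with weights
1/(se_i^2 + tau^2).

Everything is computed on the log scale; exponentiation happens only in
summaries and forest-plot data.  The models follow the statsmodels
convention: construct with data, call ``.fit()``, read the results
object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .effects import EffectEstimate, Z95

__all__ = [
    "RandomEffectsMeta",
    "MetaResults",
    "MetaRegression",
    "MetaRegressionResults",
    "dl_pool",
    "meta_regression",
    "forest_data",
    "se_from_ci",
]


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Back-compute a log-scale SE from a 95% CI on the ratio scale."""
    if not (0 < ci_low <= ci_high):
        raise ValueError("need 0 < ci_low <= ci_high on the ratio scale")
    return (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)


def _as_arrays(effects, se=None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accept a list of EffectEstimate or (y, se) arrays."""
    if se is None:
        ests = list(effects)
        if not ests:
            raise ValueError("no effects supplied")
        y = np.array([e.log_effect for e in ests], dtype=float)
        s = np.array([e.se for e in ests], dtype=float)
        labels = [e.label or f"site {i}" for i, e in enumerate(ests)]
    else:
        y = np.asarray(effects, dtype=float)
        s = np.asarray(se, dtype=float)
        labels = [f"site {i}" for i in range(y.size)]
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("effects and standard errors must be matching 1-d vectors")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(s))):
        raise ValueError("effects and standard errors must be finite")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    return y, s, labels


class RandomEffectsMeta:
    """DerSimonian-Laird random-effects pooling of k site effects.

    Parameters
    ----------
    effects : sequence of EffectEstimate, or 1-d array of log effects
    se : 1-d array of positive standard errors (when ``effects`` is an array)
    """

    def __init__(self, effects, se=None):
        self.y, self.se, self.labels = _as_arrays(effects, se)
        self.k = self.y.size
        if self.k < 2:
            raise ValueError("meta-analysis needs at least 2 sites")

    def fit(self, knapp_hartung: bool = False) -> "MetaResults":
        y, v = self.y, self.se**2
        w = 1.0 / v
        y_fe = float(np.sum(w * y) / np.sum(w))
        Q = float(np.sum(w * (y - y_fe) ** 2))
        df = self.k - 1
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
        i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0

        w_re = 1.0 / (v + tau2)
        pooled = float(np.sum(w_re * y) / np.sum(w_re))
        se_pooled = float(np.sqrt(1.0 / np.sum(w_re)))
        if knapp_hartung:
            s2 = float(np.sum(w_re * (y - pooled) ** 2) / df)
            se_pooled *= math.sqrt(max(s2, 0.0))
            crit = float(t_dist.ppf(0.975, df))
        else:
            crit = Z95
        return MetaResults(
            model=self,
            pooled_log_effect=pooled,
            se=se_pooled,
            ci_low=pooled - crit * se_pooled,
            ci_high=pooled + crit * se_pooled,
            Q=Q,
            tau2=tau2,
            I2=i2,
            k=self.k,
            knapp_hartung=knapp_hartung,
        )


@dataclass
class MetaResults:
    """Pooled random-effects estimate with heterogeneity statistics.

    CI bounds are on the log scale; ``summary()`` exponentiates.
    """

    model: RandomEffectsMeta = field(repr=False)
    pooled_log_effect: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    tau2: float
    I2: float
    k: int
    knapp_hartung: bool = False

    def as_effect(self, label: str = "pooled") -> EffectEstimate:
        return EffectEstimate(
            log_effect=self.pooled_log_effect,
            se=self.se,
            ci_low=math.exp(self.ci_low),
            ci_high=math.exp(self.ci_high),
            measure_kind="pooled",
            label=label,
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [self.k],
                "pooled_ratio": [math.exp(self.pooled_log_effect)],
                "ci_low": [math.exp(self.ci_low)],
                "ci_high": [math.exp(self.ci_high)],
                "log_effect": [self.pooled_log_effect],
                "se": [self.se],
                "Q": [self.Q],
                "tau2": [self.tau2],
                "I2_pct": [self.I2],
            }
        )


class MetaRegression:
    """Method-of-moments meta-regression of site effects on a covariate.

    The covariate is typically an implementation-strength score in
    [0, 1]; the slope is then the change in log effect per unit score,
    reported also as a ratio (exponentiated slope).

    Parameters
    ----------
    effects : sequence of EffectEstimate or 1-d array of log effects
    covariate : 1-d array, one value per site
    se : standard errors when ``effects`` is an array
    """

    def __init__(self, effects, covariate, se=None):
        self.y, self.se, self.labels = _as_arrays(effects, se)
        self.x = np.asarray(covariate, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("covariate must have one value per site")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("covariate must be finite")
        self.k = self.y.size
        if self.k < 3:
            raise ValueError("meta-regression needs at least 3 sites")
        if np.ptp(self.x) == 0:
            raise ValueError("constant covariate: slope is not identifiable")

    def fit(self, knapp_hartung: bool = False) -> "MetaRegressionResults":
        y, v, x = self.y, self.se**2, self.x
        k = self.k
        X = np.column_stack([np.ones(k), x])
        p = X.shape[1]

        # Moment estimator of residual heterogeneity from the
        # fixed-effect WLS residual Q-statistic:
        # tau2 = max(0, (Q_E - (k - p)) / tr(P)),  P = W - WX(X'WX)^-1 X'W.
        W = np.diag(1.0 / v)
        XtWX = X.T @ W @ X
        if np.linalg.cond(XtWX) > 1e12:
            raise ValueError("design is numerically singular (collinear covariate)")
        H = X @ np.linalg.solve(XtWX, X.T @ W)
        P = W - W @ H
        Q_E = float(y @ P @ y)
        trP = float(np.trace(P))
        tau2 = max(0.0, (Q_E - (k - p)) / trP) if trP > 0 else 0.0

        w_star = 1.0 / (v + tau2)
        Ws = np.diag(w_star)
        cov = np.linalg.inv(X.T @ Ws @ X)
        beta = cov @ (X.T @ (w_star * y))
        resid = y - X @ beta
        if knapp_hartung:
            s2 = float(np.sum(w_star * resid**2) / (k - p))
            cov = cov * max(s2, 0.0)
            crit = float(t_dist.ppf(0.975, k - p))
        else:
            crit = Z95
        slope_se = float(np.sqrt(cov[1, 1]))
        return MetaRegressionResults(
            model=self,
            intercept=float(beta[0]),
            slope=float(beta[1]),
            slope_se=slope_se,
            slope_ci=(float(beta[1]) - crit * slope_se, float(beta[1]) + crit * slope_se),
            tau2_resid=tau2,
            Q_E=Q_E,
            cov=cov,
            knapp_hartung=knapp_hartung,
        )


@dataclass
class MetaRegressionResults:
    """WLS meta-regression coefficients with residual heterogeneity."""

    model: MetaRegression = field(repr=False)
    intercept: float
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    tau2_resid: float
    Q_E: float
    cov: np.ndarray = field(repr=False)
    knapp_hartung: bool = False

    @property
    def or_per_unit(self) -> float:
        """Exponentiated slope: ratio change per unit of the covariate."""
        return math.exp(self.slope)

    @property
    def or_per_unit_ci(self) -> tuple[float, float]:
        return (math.exp(self.slope_ci[0]), math.exp(self.slope_ci[1]))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.or_per_unit_ci
        return pd.DataFrame(
            {
                "term": ["intercept", "slope"],
                "estimate": [self.intercept, self.slope],
                "se": [float(np.sqrt(self.cov[0, 0])), self.slope_se],
                "ratio_per_unit": [math.exp(self.intercept), self.or_per_unit],
                "ci_low": [np.nan, lo],
                "ci_high": [np.nan, hi],
                "tau2_resid": [self.tau2_resid] * 2,
            }
        )


def dl_pool(effects, se=None, knapp_hartung: bool = False) -> MetaResults:
    """DerSimonian-Laird pooling (functional wrapper over RandomEffectsMeta)."""
    return RandomEffectsMeta(effects, se).fit(knapp_hartung=knapp_hartung)


def meta_regression(effects, covariate, se=None, knapp_hartung: bool = False) -> MetaRegressionResults:
    """Method-of-moments meta-regression (functional wrapper)."""
    return MetaRegression(effects, covariate, se).fit(knapp_hartung=knapp_hartung)


def forest_data(effects, pooled: MetaResults | None = None) -> pd.DataFrame:
    """Per-site rows plus a pooled diamond row, on the display (ratio) scale.

    If ``pooled`` is omitted it is computed by ``dl_pool``.
    """
    y, s, labels = _as_arrays(effects)
    if pooled is None:
        pooled = dl_pool(y, s)
    rows = [
        {
            "label": lab,
            "kind": "site",
            "estimate": math.exp(yi),
            "ci_low": math.exp(yi - Z95 * si),
            "ci_high": math.exp(yi + Z95 * si),
            "log_effect": yi,
            "se": si,
            "weight_pct": float(wi),
        }
        for lab, yi, si, wi in zip(
            labels, y, s, 100 * (1 / (s**2 + pooled.tau2)) / np.sum(1 / (s**2 + pooled.tau2))
        )
    ]
    rows.append(
        {
            "label": "pooled (random effects)",
            "kind": "pooled",
            "estimate": math.exp(pooled.pooled_log_effect),
            "ci_low": math.exp(pooled.ci_low),
            "ci_high": math.exp(pooled.ci_high),
            "log_effect": pooled.pooled_log_effect,
            "se": pooled.se,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
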