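"""Cluster-period logistic fits for stepped-wedge event tables.

The unit of analysis is the cluster-period cell: ``events`` adverse
outcomes out of ``deliveries`` in cluster *c* at calendar period *t*,
with a 0/1 treatment indicator that switches on at the cluster's
crossover and stays on.  The model is a binomial logistic regression

    logit p_ct = centre effect(s) + linear period trend(s) + beta * treated_ct

fitted by Newton-Raphson iteratively reweighted least squares (IRLS)
with step-halving, to an absolute score-vector tolerance.  Marginal
(population-averaged) inference across clusters uses an
independence working model with a cluster-robust sandwich covariance
and the small-sample factor G/(G-1); the point estimates coincide with
the independence-working GEE solution.

Three design specifications are available:

``"site"``
    intercept + centred period trend + treatment — the per-site model
    whose treatment coefficient feeds the meta-analysis;
``"pooled"``
    one intercept and one centred trend per centre + a common treatment
    effect (separate fixed linear trends in each centre);
``"pooled_common_trend"``
    centre intercepts + a single shared trend + treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .effects import EffectEstimate, Z95

__all__ = [
    "ClusterPeriodLogit",
    "ClusterPeriodLogitResults",
    "fit_logistic",
    "cluster_robust_cov",
    "site_effect",
    "validate_cells",
]

FORMULAS = ("site", "site_no_trend", "pooled", "pooled_common_trend")


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cluster-period table invariants and return a clean copy.

    Requires columns ``cluster_id, period, treated, deliveries,
    events``; enforces count bounds and stepped-wedge monotonicity of
    treatment within each cluster (once treated, always treated).
    """
    required = ["cluster_id", "period", "treated", "deliveries", "events"]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise ValueError(f"cluster-period table missing columns: {missing}")
    df = cells[required].copy()
    if df[["period", "deliveries", "events"]].isna().any().any():
        raise ValueError("cluster-period table contains missing values")
    if (df["deliveries"] < 0).any() or (df["events"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (df["events"] > df["deliveries"]).any():
        raise ValueError("events cannot exceed deliveries in any cell")
    if not df["treated"].isin([0, 1]).all():
        raise ValueError("treated must be 0/1")
    for cid, sub in df.sort_values("period").groupby("cluster_id"):
        if (np.diff(sub["treated"].to_numpy()) < 0).any():
            raise ValueError(f"cluster {cid!r}: treatment switches off (violates stepped-wedge monotonicity)")
    return df


def _design_matrix(df: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    period_c = df["period"].to_numpy(float) - df["period"].to_numpy(float).mean()
    treated = df["treated"].to_numpy(float)
    if formula == "site":
        X = np.column_stack([np.ones(len(df)), period_c, treated])
        return X, ["intercept", "trend", "treated"]
    if formula == "site_no_trend":
        X = np.column_stack([np.ones(len(df)), treated])
        return X, ["intercept", "treated"]
    clusters = sorted(df["cluster_id"].unique())
    dummies = np.column_stack([(df["cluster_id"] == c).to_numpy(float) for c in clusters])
    names = [f"centre[{c}]" for c in clusters]
    if formula == "pooled":
        trends = dummies * period_c[:, None]
        X = np.column_stack([dummies, trends, treated])
        names += [f"trend[{c}]" for c in clusters] + ["treated"]
    else:
        X = np.column_stack([dummies, period_c, treated])
        names += ["trend", "treated"]
    return X, names


class ClusterPeriodLogit:
    """Binomial logistic model on cluster-period cells.

    Parameters
    ----------
    cells : DataFrame
        Long table with columns ``cluster_id, period, treated,
        deliveries, events`` (one row per cluster-period cell).
    formula : {"site", "pooled", "pooled_common_trend"}
        Design specification (see module docstring).
    """

    def __init__(self, cells: pd.DataFrame, formula: str = "pooled"):
        self.cells = validate_cells(cells)
        self.formula = formula
        self.exog, self.exog_names = _design_matrix(self.cells, formula)
        self.n_trials = self.cells["deliveries"].to_numpy(float)
        self.endog = self.cells["events"].to_numpy(float)
        if self.endog.sum() == 0 or (self.n_trials - self.endog).sum() == 0:
            raise ValueError("need at least one event and one non-event overall")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def from_dataframe(cls, cells: pd.DataFrame, formula: str = "pooled") -> "ClusterPeriodLogit":
        return cls(cells, formula=formula)

    def loglike(self, beta: np.ndarray) -> float:
        """Binomial log-likelihood up to the fixed combinatorial constant."""
        eta = self.exog @ beta
        return float(np.sum(self.endog * eta - self.n_trials * np.logaddexp(0.0, eta)))

    def score(self, beta: np.ndarray) -> np.ndarray:
        mu = self.n_trials * expit(self.exog @ beta)
        return self.exog.T @ (self.endog - mu)

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ beta)
        w = self.n_trials * p * (1.0 - p)
        return -(self.exog * w[:, None]).T @ self.exog

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "ClusterPeriodLogitResults":
        """Maximise the likelihood by Newton IRLS with step-halving.

        Convergence is declared when the largest absolute component of
        the score vector drops below ``tol``.  Diverging coefficients
        (complete or quasi-separation) leave ``converged = False``.
        """
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll = self.loglike(beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            g = self.score(beta)
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            H = self.hessian(beta)
            # ridge fallback if curvature degenerates (e.g. p -> 0 or 1)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(-H + 1e-8 * np.eye(p), g)
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta = beta + scale * step
            ll = self.loglike(beta)
        else:
            it = max_iter
        # |beta| beyond any plausible log-odds for count data flags
        # (quasi-)separation: the likelihood flattens while coefficients
        # diverge, so the gradient criterion alone can be met spuriously
        if np.max(np.abs(beta)) > 15:
            converged = False
        H = self.hessian(beta)
        cov = np.linalg.inv(-H + (0.0 if converged else 1e-8) * np.eye(p))
        return ClusterPeriodLogitResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            converged=converged,
            n_iterations=it,
            log_likelihood=ll,
        )


@dataclass
class ClusterPeriodLogitResults:
    """IRLS fit results: coefficients, covariances and diagnostics."""

    model: ClusterPeriodLogit = field(repr=False)
    params: pd.Series
    cov_params: pd.DataFrame = field(repr=False)
    converged: bool
    n_iterations: int
    log_likelihood: float

    @property
    def bse(self) -> pd.Series:
        """Model-based (inverse Fisher information) standard errors."""
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    def cluster_robust_cov(self, groups=None) -> pd.DataFrame:
        """Cluster-robust sandwich covariance with G/(G-1) correction.

        ``groups`` defaults to the table's ``cluster_id``; passing a
        finer grouping (one group per cell) yields the
        heteroscedasticity-robust form.
        """
        m = self.model
        if groups is None:
            groups = m.cells["cluster_id"].to_numpy()
        groups = np.asarray(groups)
        if groups.shape[0] != m.exog.shape[0]:
            raise ValueError("groups must have one entry per cell")
        uniq = pd.unique(groups)
        G = uniq.size
        if G < 2:
            raise ValueError("cluster-robust covariance needs at least 2 clusters")
        beta = self.params.to_numpy()
        resid = m.endog - m.n_trials * expit(m.exog @ beta)
        scores = m.exog * resid[:, None]
        B = np.zeros((beta.size, beta.size))
        for gval in uniq:
            sg = scores[groups == gval].sum(axis=0)
            B += np.outer(sg, sg)
        A_inv = self.cov_params.to_numpy()
        cov = A_inv @ B @ A_inv * (G / (G - 1))
        return pd.DataFrame(cov, index=self.params.index, columns=self.params.index)

    @property
    def bse_robust(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cluster_robust_cov().to_numpy())), index=self.params.index
        )

    def treatment_effect(self, robust: bool = False, label: str = "") -> EffectEstimate:
        """Package the treatment coefficient as a log-OR EffectEstimate."""
        est = float(self.params["treated"])
        se = float((self.bse_robust if robust else self.bse)["treated"])
        return EffectEstimate(
            log_effect=est,
            se=se,
            ci_low=float(np.exp(est - Z95 * se)),
            ci_high=float(np.exp(est + Z95 * se)),
            measure_kind="odds_ratio",
            label=label,
        )

    def summary(self, robust: bool = False) -> pd.DataFrame:
        se = self.bse_robust if robust else self.bse
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se_model": self.bse.to_numpy(),
                "se_robust" if robust else "se": se.to_numpy(),
                "odds_ratio": np.exp(self.params.to_numpy()),
                "ci_low": np.exp(self.params.to_numpy() - Z95 * se.to_numpy()),
                "ci_high": np.exp(self.params.to_numpy() + Z95 * se.to_numpy()),
            }
        ).reset_index(drop=True)


def fit_logistic(cells: pd.DataFrame, formula: str = "pooled", **fit_kwargs) -> ClusterPeriodLogitResults:
    """Fit the cluster-period logistic model (functional wrapper)."""
    return ClusterPeriodLogit(cells, formula=formula).fit(**fit_kwargs)


def cluster_robust_cov(fit: ClusterPeriodLogitResults, groups=None) -> pd.DataFrame:
    """Cluster-robust sandwich covariance of a converged fit."""
    if not fit.converged:
        raise ValueError("robust covariance requires a converged fit")
    return fit.cluster_robust_cov(groups)


def site_effect(cells: pd.DataFrame, label: str = "") -> EffectEstimate:
    """Per-site intervention log-OR, adjusted for a linear period trend.

    Fits intercept + centred trend + treatment on one site's
    cluster-period cells and returns the treatment coefficient with its
    model-based standard error, ready for meta-analysis.
    """
    df = validate_cells(cells)
    sites = df["cluster_id"].unique()
    if sites.size != 1:
        raise ValueError("site_effect expects cells from exactly one site")
    exposed = df.loc[df["deliveries"] > 0, "treated"]
    if exposed.nunique() < 2:
        raise ValueError(
            f"site {sites[0]!r} lacks both control and intervention periods with deliveries"
        )
    res = ClusterPeriodLogit(df, formula="site").fit()
    if not res.converged:
        raise RuntimeError(f"site {sites[0]!r}: logistic fit did not converge (possible separation)")
    return res.treatment_effect(label=label or str(sites[0]))
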