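"""Synthetic stepped-wedge trial and process-measure generator.

Emulates a multi-country maternity trial in which each cluster-period
cell records a number of deliveries and a count of rare composite
adverse events (order 10-100 per 10,000 deliveries).  Events are
binomial with a logit-linear cell probability

    logit(p_ct) = logit(base rate) + centre_effect_c
                  + centre_trend_c * period + log_OR * treated_ct

so the generator has exactly the structure the cluster-period logistic
fit assumes: fixed centre effects, centre-specific linear calendar
trends, and a common treatment log odds ratio.  Deliveries per cell are
Poisson around a per-cluster monthly mean.

Quantitative implementation measures (the inputs to the rank-based
composite score) are generated per cluster on natural proportion
scales, grouped into the fidelity / reach / adoption domains, with an
optional *coupling* that ties a cluster's measures to its true
treatment effect — used for recovery experiments in which the
score-vs-effect meta-regression slope has a known sign.

Seeding: a single integer seed is split into independent streams with
``numpy.random.SeedSequence.spawn`` — stream 0 drives the design
allocation, stream 1 the trial counts, stream 2 the implementation
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import Design, generate_design

__all__ = [
    "SimParams",
    "split_seed",
    "simulate_trial",
    "simulate_implementation",
    "simulate_study",
    "MEASURE_LAYOUT",
]


def split_seed(seed: int, n: int = 3) -> list[np.random.Generator]:
    """Split one integer seed into ``n`` independent generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SimParams:
    """Data-generating parameters for one synthetic trial.

    Parameters
    ----------
    baseline_event_rate : float
        Control-condition event probability per delivery, in (0, 1).
        The emulated trial's composite outcome ran at roughly 40-320
        events per 10,000 deliveries across sites.
    treatment_log_or : float
        Common treatment effect on the log-odds scale.
    centre_effects : array-like, per cluster
        Fixed log-odds offsets from the baseline rate (site case-mix).
    centre_trends : array-like, per cluster
        Log-odds change per calendar period (secular trends).
    deliveries_per_period : array-like, per cluster
        Mean deliveries per cluster-period cell (Poisson).
    implementation_coupling : float
        Slope tying implementation measures to the cluster's true
        effect; 0 means measures carry no effectiveness signal.
    implementation_noise_sd : float
        Between-cluster noise on the latent implementation strength.
    seed : int
        Master seed; split internally into independent streams.
    """

    baseline_event_rate: float = 0.01
    treatment_log_or: float = 0.0
    centre_effects: np.ndarray | None = None
    centre_trends: np.ndarray | None = None
    deliveries_per_period: np.ndarray | None = None
    implementation_coupling: float = 0.0
    implementation_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_event_rate < 1.0:
            raise ValueError("baseline_event_rate must be in (0, 1)")
        for name in ("treatment_log_or", "implementation_coupling"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.implementation_noise_sd < 0:
            raise ValueError("implementation_noise_sd must be >= 0")

    def resolve(self, n_clusters: int) -> "SimParams":
        """Fill per-cluster defaults (zeros / 1000 deliveries) and validate lengths."""
        def vec(x, default):
            if x is None:
                return np.full(n_clusters, float(default))
            x = np.asarray(x, dtype=float)
            if x.shape != (n_clusters,):
                raise ValueError(f"per-cluster parameter has length {x.size}, expected {n_clusters}")
            if not np.all(np.isfinite(x)):
                raise ValueError("per-cluster parameters must be finite")
            return x

        out = SimParams(**{**self.__dict__})
        out.centre_effects = vec(self.centre_effects, 0.0)
        out.centre_trends = vec(self.centre_trends, 0.0)
        out.deliveries_per_period = vec(self.deliveries_per_period, 1000.0)
        if out.deliveries_per_period.min() < 1:
            raise ValueError("mean deliveries per period must be >= 1")
        return out


def simulate_trial(
    design: Design,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one cluster-period event table from the design.

    Returns a long DataFrame with columns ``cluster_id, period,
    treated, deliveries, events``.  Cells that happen to draw zero
    deliveries keep ``events = 0`` and are retained (they are
    non-informative in the binomial likelihood, not invalid).
    """
    params = params.resolve(design.n_clusters)
    if rng is None:
        rng = split_seed(params.seed)[1]
    alpha = logit(params.baseline_event_rate) + params.centre_effects
    treat = design.treatment_matrix()
    periods = np.arange(design.n_periods)

    frames = []
    for c in range(design.n_clusters):
        eta = alpha[c] + params.centre_trends[c] * periods + params.treatment_log_or * treat[c]
        p = expit(eta)
        deliveries = rng.poisson(params.deliveries_per_period[c], size=design.n_periods)
        events = rng.binomial(deliveries, p)
        frames.append(
            pd.DataFrame(
                {
                    "cluster_id": c,
                    "period": periods,
                    "treated": treat[c],
                    "deliveries": deliveries,
                    "events": events,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# Measure layout mirrors the quantitative process measures a hybrid
# effectiveness-implementation trial collects: what fraction of staff
# was trained (fidelity), how exposed women and facilities were to the
# intervention (reach), and routine uptake at 6 months (adoption).
# ``base`` is the logit-scale location of the proportion, ``sign`` the
# direction in which higher latent implementation strength moves it.
MEASURE_LAYOUT = [
    ("staff_trained_prop", "fidelity", "higher_is_better", 0.5, +1),
    ("training_content_prop", "fidelity", "higher_is_better", 1.5, +1),
    ("bp_measured_post_prop", "reach", "higher_is_better", 2.0, +1),
    ("facilities_equipped_prop", "reach", "higher_is_better", 2.5, +1),
    ("devices_broken_prop", "reach", "lower_is_better", -3.0, -1),
    ("sole_device_use_6mo_prop", "adoption", "higher_is_better", 1.0, +1),
]


def simulate_implementation(
    design: Design,
    coupling: float = 0.0,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    true_log_or: np.ndarray | None = None,
    measure_noise_sd: float = 0.25,
    adoption_missing: int = 2,
) -> pd.DataFrame:
    """Generate per-cluster quantitative implementation measures.

    Each cluster gets a latent implementation strength
    ``s_c = -coupling * true_log_or_c + N(0, noise_sd^2)`` (a protective
    effect, i.e. a more negative log-OR, maps to higher strength when
    ``coupling > 0``), and each measure is a logistic transform of the
    latent strength plus measure-level noise.  With ``coupling = 0`` the
    measures are independent of the true effects; with
    ``noise_sd = measure_noise_sd = 0`` the composite-score ordering is
    exactly the ordering by effect magnitude.

    ``adoption_missing`` clusters (the last ones to cross over, whose
    6-month review fell beyond the trial window) have their adoption
    measure marked unavailable — the stepped-wedge right-censoring a
    real rollout produces.

    Returns a long DataFrame with columns ``cluster_id, measure_name,
    domain, direction, value, available``.
    """
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    if noise_sd < 0 or measure_noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    if coupling != 0.0 and true_log_or is None:
        raise ValueError("coupling != 0 requires per-cluster true_log_or")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = design.n_clusters
    effects = np.zeros(n) if true_log_or is None else np.asarray(true_log_or, dtype=float)
    if effects.shape != (n,):
        raise ValueError("true_log_or must have one entry per cluster")
    latent = -coupling * effects + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)

    # Clusters with the latest crossovers never reach their 6-month review.
    order = np.argsort(-design.crossover_period, kind="stable")
    censored = set(order[:adoption_missing].tolist()) if adoption_missing > 0 else set()

    rows = []
    for name, domain, direction, base, sign in MEASURE_LAYOUT:
        eps = rng.normal(0.0, measure_noise_sd, size=n) if measure_noise_sd > 0 else np.zeros(n)
        values = expit(base + sign * latent + eps)
        for c in range(n):
            available = not (domain == "adoption" and c in censored)
            rows.append(
                {
                    "cluster_id": c,
                    "measure_name": name,
                    "domain": domain,
                    "direction": direction,
                    "value": float(values[c]) if available else np.nan,
                    "available": available,
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    n_clusters: int = 10,
    n_steps: int = 9,
    periods_per_step: int = 1,
    params: SimParams | None = None,
    seed: int | None = None,
) -> tuple[Design, pd.DataFrame, pd.DataFrame]:
    """One-call generator: design + trial table + implementation table.

    Defaults emulate the reference trial footprint: 10 clusters crossing
    over in 9 steps (one all-control lead-in period, 10 two-month
    periods over 20 months).
    """
    params = params or SimParams()
    if seed is not None:
        params = SimParams(**{**params.__dict__, "seed": seed})
    rng_design, rng_trial, rng_impl = split_seed(params.seed)
    design = generate_design(n_clusters, n_steps, periods_per_step, seed=rng_design)
    cells = simulate_trial(design, params, rng=rng_trial)
    resolved = params.resolve(n_clusters)
    measures = simulate_implementation(
        design,
        coupling=resolved.implementation_coupling,
        noise_sd=resolved.implementation_noise_sd,
        seed=rng_impl,
        true_log_or=np.full(n_clusters, resolved.treatment_log_or),
    )
    return design, cells, measures
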