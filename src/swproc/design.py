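"""Stepped-wedge design construction.

A stepped-wedge cluster randomised trial starts every cluster in the
control condition and crosses clusters over to the intervention at
staggered, randomly assigned time steps, so that calendar time and
treatment are partially confounded by design and every cluster
eventually receives the intervention.

The design grid here is indexed by 0-based calendar *periods*.  A trial
with ``n_steps`` steps and ``periods_per_step`` periods between
consecutive crossovers spans ``(n_steps + 1) * periods_per_step``
periods: period 0 (and any further pre-rollout periods) is all-control,
and a cluster allocated to step ``s`` (1-based) is treated from period
``s * periods_per_step`` onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Design", "generate_design"]


@dataclass(frozen=True)
class Design:
    """A stepped-wedge treatment schedule.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (sites).
    n_steps : int
        Number of crossover steps.
    periods_per_step : int
        Calendar periods between consecutive crossovers.
    crossover_period : ndarray of int, shape (n_clusters,)
        First treated period of each cluster (0-based calendar index).
    """

    n_clusters: int
    n_steps: int
    periods_per_step: int
    crossover_period: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        xo = np.asarray(self.crossover_period, dtype=int)
        object.__setattr__(self, "crossover_period", xo)
        if self.n_clusters < 1 or self.n_steps < 2 or self.periods_per_step < 1:
            raise ValueError("need n_clusters >= 1, n_steps >= 2, periods_per_step >= 1")
        if xo.shape != (self.n_clusters,):
            raise ValueError("crossover_period must have one entry per cluster")
        if xo.min() < 1 or xo.max() > self.n_steps * self.periods_per_step:
            raise ValueError("crossover periods must lie on the step grid")

    @property
    def n_periods(self) -> int:
        return (self.n_steps + 1) * self.periods_per_step

    def treated(self, cluster: int, period: int) -> int:
        """Treatment indicator for one cluster-period cell."""
        return int(period >= self.crossover_period[cluster])

    def treatment_matrix(self) -> np.ndarray:
        """(n_clusters, n_periods) 0/1 array of treatment status."""
        periods = np.arange(self.n_periods)
        return (periods[None, :] >= self.crossover_period[:, None]).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format cluster x period lattice with treatment indicator."""
        mat = self.treatment_matrix()
        rows = [
            {"cluster_id": c, "period": t, "treated": int(mat[c, t])}
            for c in range(self.n_clusters)
            for t in range(self.n_periods)
        ]
        return pd.DataFrame(rows)


def generate_design(
    n_clusters: int,
    n_steps: int,
    periods_per_step: int = 1,
    seed: int | np.random.Generator = 0,
) -> Design:
    """Randomly allocate clusters to crossover steps.

    Each step receives ``floor(n_clusters / n_steps)`` clusters; any
    remainder is assigned round-robin to the earliest steps, and the
    mapping of clusters to step slots is a seeded uniform permutation.
    The allocation is balanced whenever ``n_clusters`` is a multiple of
    ``n_steps``, and every cluster keeps at least one control period.

    Parameters
    ----------
    n_clusters, n_steps, periods_per_step : int
        Grid dimensions; requires ``n_clusters >= n_steps >= 2``.
    seed : int or numpy Generator
        Seeds the allocation permutation.
    """
    if n_steps < 2:
        raise ValueError("a stepped-wedge design needs at least 2 steps")
    if n_clusters < n_steps:
        raise ValueError(
            f"cannot fill {n_steps} steps with {n_clusters} clusters: "
            "every step must receive at least one cluster"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    reps = -(-n_clusters // n_steps)  # ceil
    slots = np.tile(np.arange(1, n_steps + 1), reps)[:n_clusters]
    steps = slots[rng.permutation(n_clusters)]
    return Design(
        n_clusters=n_clusters,
        n_steps=n_steps,
        periods_per_step=periods_per_step,
        crossover_period=steps * periods_per_step,
    )
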