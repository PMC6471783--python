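import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from swproc import SimParams, generate_design, simulate_trial

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def reference_design():
    """The emulated trial footprint: 10 clusters, 9 steps, 10 periods."""
    return generate_design(10, 9, 1, seed=1)


@pytest.fixture
def small_trial(reference_design):
    """One seeded trial draw with a protective treatment effect."""
    params = SimParams(
        baseline_event_rate=0.01,
        treatment_log_or=np.log(0.7),
        centre_effects=np.linspace(-0.3, 0.3, 10),
        centre_trends=np.full(10, -0.01),
        deliveries_per_period=np.full(10, 2000.0),
        seed=42,
    )
    return simulate_trial(reference_design, params)


@pytest.fixture
def flat_cells():
    """Deterministic cluster-period table with a constant 10% event rate."""
    rows = []
    for c in range(4):
        for t in range(6):
            rows.append(
                {
                    "cluster_id": c,
                    "period": t,
                    "treated": int(t >= c + 1),
                    "deliveries": 1000,
                    "events": 100,
                }
            )
    return pd.DataFrame(rows)
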