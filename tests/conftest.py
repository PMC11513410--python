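"""Shared fixtures: one synthetic study system and one reduced-cost fit.

Everything is generated programmatically with fixed seeds; the heavier
fixtures are session-scoped so several test modules can share one
simulation and one MCMC run.
"""

import numpy as np
import pytest

from isdm_change import (
    IntegratedSDM,
    SimulationConfig,
    assemble_isdm_data,
    simulate_po,
    simulate_surveys,
)
from isdm_change.synthetic import default_truth


@pytest.fixture(scope="session")
def study():
    """A complete default synthetic system (20x20 grid, 30 surveys)."""
    cfg = SimulationConfig(seed=3)
    truth = default_truth(cfg)
    counts, records = simulate_po(truth, cfg)
    surveys, blobs, detections = simulate_surveys(truth, cfg)
    data = assemble_isdm_data(
        truth.grid, counts, blobs, cfg.species, cfg.effort_ratio_true, cfg.period_split_year
    )
    return {
        "config": cfg,
        "truth": truth,
        "counts": counts,
        "records": records,
        "surveys": surveys,
        "blobs": blobs,
        "detections": detections,
        "data": data,
    }


@pytest.fixture(scope="session")
def fitted(study):
    """A reduced-iteration fit of the default system, reused across tests."""
    est = IntegratedSDM(iterations=700, max_leapfrog=24, chains=4, random_state=1)
    est.fit(study["data"])
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
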