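"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import vigblup as v

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """One simulated site-year small enough for quick model fits."""
    cfg = v.SimulationConfig(
        n_hybrids=80, n_maternal=12, n_paternal=12, n_markers=300, seed=20260901
    )
    return v.simulate_dataset(cfg)


def make_st_pheno(n_hybrids, sigma_a2, sigma_e2, seed, n_reps=2, mean=100.0):
    """Plot table for a single trait with iid hybrid genetic values."""
    rng = np.random.default_rng(seed)
    hybrids = [f"H{i:04d}" for i in range(n_hybrids)]
    g = rng.normal(0.0, np.sqrt(sigma_a2), n_hybrids) if sigma_a2 > 0 else np.zeros(n_hybrids)
    rows = []
    for rep in range(1, n_reps + 1):
        e = rng.normal(0.0, np.sqrt(sigma_e2), n_hybrids)
        for i, h in enumerate(hybrids):
            rows.append(
                {
                    "plot_id": f"r{rep}_{i:04d}",
                    "hybrid_id": h,
                    "replicate": f"rep{rep}",
                    "y": mean + (2.0 if rep == 2 else 0.0) + g[i] + e[i],
                }
            )
    return pd.DataFrame(rows), hybrids, g
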