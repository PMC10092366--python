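import numpy as np
import pandas as pd
import pytest

from fastslow.synthdata import SimConfig, generate


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic synthetic dataset shared across tests."""
    cfg = SimConfig(n_species=20, n_populations=60, n_sites=25, seed=42,
                    missing_rate=0.1, zero_rate=0.02)
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, gap-free dataset: series follow the trend model exactly."""
    cfg = SimConfig(n_species=15, n_populations=50, n_sites=20, seed=7,
                    missing_rate=0.0, zero_rate=0.0, sigma_resid=0.0)
    return generate(cfg)


def truth_frame(sim, noise_sd=0.005, seed=1):
    """Model frame straight from a SimData's ground truth (+response noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid, (sp, sid) in sim.truth.pop_assignments.items():
        row = {"population_id": pid, "species": sp, "location_id": sid,
               "mean_lambda": sim.truth.pop_lambda[pid]
               + rng.normal(0, noise_sd),
               "delta_t": sim.truth.temp_slopes[sid],
               "pc1": sim.truth.latent_fastslow[sp]}
        row.update({f"lc_{c}": r
                    for c, r in sim.truth.cover_rates[sid].items()})
        rows.append(row)
    return pd.DataFrame(rows)
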