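import numpy as np
import pandas as pd
import pytest

import stproj as sp


@pytest.fixture(scope="session")
def printed_model() -> sp.SeparableCovModel:
    """Separable model with the published parameters (c0=1, 10 km, 2 yr)."""
    return sp.SeparableCovModel(c0=1.0, alpha_s=10_000.0, alpha_t=2.0)


@pytest.fixture(scope="session")
def small_field() -> sp.SimulatedField:
    """A quick traveling field for pipeline smoke tests (80 towns x 3 years)."""
    cfg = sp.SimulationConfig(
        n_locations=80,
        years=(2008, 2009, 2010),
        speed=-6000.0,
        sill=0.5,
        trend_amplitude=1.5,
        mean_log=3.0,
        seed=42,
    )
    return sp.simulate_traveling_field(cfg)


@pytest.fixture()
def incidence_df() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 30
    return pd.DataFrame(
        {
            "town_id": [f"t{i:04d}" for i in range(n)],
            "x_m": rng.uniform(0, 50_000, n),
            "y_m": rng.uniform(0, 50_000, n),
            "year": 2008,
            "incidence_per_1e5": rng.uniform(0, 100, n),
        }
    )
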