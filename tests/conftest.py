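import numpy as np
import pandas as pd
import pytest

from milkmr.synthetic import SimulationScenario, simulate_cohort


@pytest.fixture(scope="session")
def small_scenario() -> SimulationScenario:
    return SimulationScenario(n_individuals=5_000, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return simulate_cohort(small_scenario)


def make_null_scan_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Genotype plus eight candidate confounders, all independent of genotype."""
    return pd.DataFrame(
        {
            "genotype": rng.binomial(2, 0.759, n),
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
            "income": rng.lognormal(10, 0.5, n),
            "education": rng.integers(0, 5, n).astype(float),
            "health_status": rng.integers(0, 4, n).astype(float),
            "smoking": rng.integers(0, 2, n),
            "alcohol": rng.gamma(2.0, 3.0, n),
            "coffee": rng.poisson(2.5, n).astype(float),
        }
    )
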