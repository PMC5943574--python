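import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phenosel.pipeline import run_platform_analysis
from phenosel.synthetic_data import (
    PlatformSimConfig,
    simulate_platform_experiment,
)


@pytest.fixture(scope="session")
def platform_sim():
    """One default-condition platform experiment shared across tests."""
    return simulate_platform_experiment(PlatformSimConfig(seed=11))


@pytest.fixture(scope="session")
def platform_results(platform_sim):
    dataset, truth = platform_sim
    return run_platform_analysis(dataset, fresh_weights=truth.fresh_weights)


@pytest.fixture()
def tiny_platform_csv(tmp_path):
    """A hand-written 2-plant x 3-day platform table."""
    df = pd.DataFrame({
        "plant_id": ["p1"] * 3 + ["p2"] * 3,
        "genotype": ["A"] * 3 + ["B"] * 3,
        "treatment": ["WW"] * 6,
        "replicate": [1] * 3 + [1] * 3,
        "dae": [1, 2, 3, 1, 2, 3],
        "leaf_area": [10.0, 12.0, 15.0, 11.0, 13.0, 16.0],
        "pot_weight": [5000.0, 4990.0, 4985.0, 5001.0, 4995.0, 4988.0],
    })
    path = tmp_path / "platform.csv"
    df.to_csv(path, index=False)
    return path, df
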