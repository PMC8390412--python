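import numpy as np
import pandas as pd
import pytest

from rollscore import rolling, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """~1800 measures, 300 families, constant PGS effect 0.05, ages 12-70."""
    cfg = simulate.SimConfig(n_families=300, beta_age=0.05)
    df, truth = simulate.simulate_measures(cfg, seed=11)
    return df, truth


@pytest.fixture(scope="session")
def small_standardized(small_dataset):
    df, truth = small_dataset
    return rolling.standardize(df), truth


@pytest.fixture()
def tiny_table():
    """Hand-sized 6-row table covering 2 families, 2 arrays."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "person": [0, 0, 1, 2, 3, 4],
            "family": [0, 0, 0, 1, 1, 1],
            "age": [15.0, 18.0, 40.0, 25.0, 60.0, 33.0],
            "phenotype": [0.1, -0.2, 0.5, 1.0, -1.3, 0.4],
            "pgs": [0.3, 0.3, -0.5, 1.2, -0.1, 0.8],
            "sex": [0, 1, 1, 0, 0, 1],
            "array": ["a1", "a1", "a2", "a2", "a1", "a2"],
            "wave": ["w1", "w2", "w1", "w1", "w1", "w1"],
        }
    )
    for i in range(1, 6):
        df[f"pc{i}"] = rng.standard_normal(6)
    return df
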