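import numpy as np
import pandas as pd
import pytest

from gamharm import synthetic_data as sd


@pytest.fixture(scope="session")
def small_benchmark():
    """3 cohorts x 500, 2 features, with known injected offsets."""
    cfg = sd.benchmark_config(seed=11, n_cohorts=3, n_per_cohort=500, n_features=2)
    table, truth = sd.generate(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def normal_table():
    """Single-cohort Gaussian data with a linear age trend and sex effect."""
    rng = np.random.default_rng(42)
    n = 2000
    age = rng.uniform(20, 80, n)
    sex = rng.integers(1, 3, n)
    y = 5.0 + 0.1 * age + 0.5 * (sex == 2) + rng.normal(0, 2.0, n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "cohort": "A", "age": age, "sex": sex, "y": y})


@pytest.fixture(scope="session")
def two_cohort_offset_table():
    """Two cohorts from shifted Normals (mu offsets -1, +1), shared age span."""
    rng = np.random.default_rng(7)
    n = 2000
    frames = []
    for lab, off in (("A", -1.0), ("B", 1.0)):
        age = rng.uniform(25, 75, n)
        sex = rng.integers(1, 3, n)
        y = 5.0 + 0.05 * age + off + rng.normal(0, 1.0, n)
        frames.append(pd.DataFrame({
            "subject_id": [f"{lab}{i}" for i in range(n)],
            "cohort": lab, "age": age, "sex": sex, "y": y}))
    return pd.concat(frames, ignore_index=True)
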