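import numpy as np
import pandas as pd
import pytest

from mrkit import HarmonisedSet, SimulationConfig, simulate_two_sample


def make_set(beta_x, beta_y, se_y, se_x=None, **kw) -> HarmonisedSet:
    """Build a HarmonisedSet straight from arrays (tests only)."""
    beta_x = np.asarray(beta_x, dtype=float)
    n = len(beta_x)
    if se_x is None:
        se_x = np.full(n, 1e-300)  # effectively exact exposure effects
    return HarmonisedSet(
        exposure_label=kw.get("exposure_label", "X"),
        outcome_label=kw.get("outcome_label", "Y"),
        variant_id=np.array([f"rs{i}" for i in range(n)], dtype=object),
        beta_x=beta_x,
        se_x=np.asarray(se_x, dtype=float),
        beta_y=np.asarray(beta_y, dtype=float),
        se_y=np.asarray(se_y, dtype=float),
    )


def tables_to_set(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonisedSet:
    """Fast path for simulator output, which is already allele-aligned."""
    return HarmonisedSet(
        exposure_label="exposure",
        outcome_label="outcome",
        variant_id=exposure["variant_id"].to_numpy(dtype=object),
        beta_x=exposure["beta"].to_numpy(),
        se_x=exposure["se"].to_numpy(),
        beta_y=outcome["beta"].to_numpy(),
        se_y=outcome["se"].to_numpy(),
    )


@pytest.fixture(scope="session")
def study_set() -> HarmonisedSet:
    """One harmonised instrument set at the default (study-scale) conditions."""
    exposure, outcome, _ = simulate_two_sample(SimulationConfig(seed=11))
    return tables_to_set(exposure, outcome)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_set(rng: np.random.Generator, j: int = 12) -> HarmonisedSet:
    bx = rng.normal(0.1, 0.05, j)
    theta = 0.3
    se_y = rng.uniform(0.01, 0.05, j)
    by = theta * bx + rng.normal(0, se_y)
    se_x = rng.uniform(0.005, 0.02, j)
    return make_set(bx, by, se_y, se_x=se_x)
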