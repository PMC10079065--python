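import numpy as np
import pandas as pd
import pytest

from rorde import synth


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return synth.generate_cohort(10, 10, synth.default_covariates(), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """400-gene matched dataset with 30 planted genes per class."""
    expr, truth = synth.generate_expression(
        small_cohort,
        400,
        planted=synth.PlantedSpec(n_per_class=30),
        noise=synth.NoiseSpec(4.0, 0.05),
        covariates=synth.default_covariates(),
        seed=42,
    )
    return expr, truth


@pytest.fixture(scope="session")
def noise_only_cohort() -> pd.DataFrame:
    return synth.generate_cohort(15, 15, synth.default_covariates(), seed=7)


def planted_delta(magnitude: float) -> dict[str, tuple[float, float]]:
    return {
        "contrasting_resistant_up": (0.0, magnitude),
        "contrasting_vulnerable_up": (magnitude, 0.0),
        "parallel_up": (magnitude, magnitude),
        "parallel_down": (-magnitude, -magnitude),
        "null": (0.0, 0.0),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
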