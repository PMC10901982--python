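import numpy as np
import pandas as pd
import pytest

from airscore import AnalysisConfig, CohortConfig, TrueEffects, generate_cohort


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """A 12k-subject cohort under the default (calibrated) conditions."""
    return generate_cohort(CohortConfig(n_subjects=12_000, seed=11))


@pytest.fixture(scope="session")
def large_exposure_cohort() -> pd.DataFrame:
    """100k subjects for marginal-calibration checks (exposures + survival)."""
    return generate_cohort(CohortConfig(n_subjects=100_000, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def two_group_exponential(n, hr, rate0=0.05, censor=(5.0, 15.0), seed=0):
    """Simple two-arm exponential survival frame used across tests."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    T = rng.exponential(1.0 / (rate0 * np.exp(np.log(hr) * x)))
    C = rng.uniform(*censor, n)
    return pd.DataFrame(
        {
            "x": x,
            "followup_years": np.minimum(T, C),
            "event": (T <= C).astype(int),
        }
    )
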