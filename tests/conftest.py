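import numpy as np
import pandas as pd
import pytest

from cprgam import synthetic_data as sd
from cprgam.bernoulli_gam import BasisDims, FitSettings, assign_component


def small_observations(years=(1963, 1966), seed=7, max_rows=12_000) -> pd.DataFrame:
    """A compact synthetic observation table with derived columns."""
    design = sd.default_design()
    samples = sd.generate_samples(design, range(years[0], years[1] + 1), seed=seed)
    obs = sd.simulate_observations(sd.default_truth(), samples, seed=seed + 1)
    if len(obs) > max_rows:
        obs = obs.sample(n=max_rows, random_state=seed).reset_index(drop=True)
    obs["comp"] = assign_component(obs["lat"].to_numpy())
    obs["y"] = obs["present"]
    return obs


@pytest.fixture(scope="session")
def obs_small() -> pd.DataFrame:
    return small_observations()


@pytest.fixture(scope="session")
def fast_settings() -> FitSettings:
    """Reduced basis dimensions and optimizer budget for test-sized fits."""
    return FitSettings(
        basis=BasisDims(
            k_uni=8, k_doy=8, k_tensor2=6, k_tensor3_space=5, k_tensor3_doy=6,
            k_year=5,
        ),
        optimizer_maxfev=40,
        n_starts=1,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
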