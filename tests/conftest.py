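import warnings

import pytest

from gxepred import SimulationConfig, simulate_dataset

# zero-variance EC warnings etc. are expected on tiny fixtures
warnings.filterwarnings("ignore", message="dropping")


@pytest.fixture(scope="session")
def small_config():
    """A miniature but structurally complete trial network."""
    return SimulationConfig(
        seed=11, n_founders=12, n_generations=3, n_genotypes=60,
        n_markers=500, n_years=5, trials_per_year_range=(4, 5),
        n_locations=8, mean_window_years=3.0, ensemble_members=3,
        projection_years=5, first_year=2001, future_first_year=2050)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def medium_dataset():
    """A trial network large enough for parameter-recovery checks
    (~150 genotypes, ~55 environments over 10 years)."""
    cfg = SimulationConfig(
        seed=21, n_founders=20, n_generations=4, n_genotypes=150,
        n_markers=600, n_years=10, trials_per_year_range=(5, 6),
        n_locations=9, mean_window_years=3.0, ensemble_members=2,
        projection_years=2)
    return simulate_dataset(cfg)
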