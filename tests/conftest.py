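import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from m6apattern import SimulationParams, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Reference synthetic cohort at the default study conditions."""
    return simulate_cohort(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A lighter cohort for tests that only need the structure, not power."""
    return simulate_cohort(
        SimulationParams(
            seed=5,
            n_samples=120,
            n_deg=60,
            n_background=100,
            markers_per_cell_type=6,
        )
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    """The small cohort written out in the pipeline's file formats."""
    from m6apattern import write_cohort

    path = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
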