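import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nicospec import LeafModelParams, SpectraSet, canonical_grid, generate_dataset
from nicospec.grid import WavelengthGrid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return canonical_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """A 50-channel VNIR grid, cheap enough for the brute-force oracle."""
    return WavelengthGrid(400, 890, 10)


@pytest.fixture
def random_set(coarse_grid):
    """30 seeded random spectra + log-normal concentrations on the coarse grid."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.05, 0.95, size=(30, coarse_grid.n_channels))
    conc = rng.lognormal(np.log(10_000), 0.7, size=30)
    spectra = SpectraSet(
        sample_ids=[f"s{i:02d}" for i in range(30)], values=values, grid=coarse_grid
    )
    return spectra, conc


@pytest.fixture(scope="session")
def noise_free_hyper(grid):
    """60 noise-free hydrated hyperaccumulator spectra on the canonical grid."""
    leaf = LeafModelParams(noise_sd=0.0)
    spectra, meta = generate_dataset(
        60, 0, state="hydrated", leaf_params=leaf, seed=5, grid=grid
    )
    return spectra, meta
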