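import numpy as np
import pytest

from organquant import synthdata as sd


@pytest.fixture
def mixed_island_spec() -> sd.OrganImageSpec:
    """One singular + two clustered islands; ground-truth SPOI = 0.5, WPOI 4."""
    return sd.OrganImageSpec(
        n_singular_islands=1,
        n_clustered_islands=2,
        island_depths_px=(80, 180, 280),
        island_radii_px=(23, 29, 30),
        seed=3,
    )


@pytest.fixture
def mixed_island_image(mixed_island_spec):
    return sd.generate_organ_image(mixed_island_spec)


@pytest.fixture
def sheet_only_spec() -> sd.OrganImageSpec:
    return sd.OrganImageSpec(seed=1)


@pytest.fixture
def gradient_ct_table():
    """Noise-free six-population Ct table on a strict latent p-EMT gradient."""
    spec = sd.CtGeneratorSpec(
        n_populations=6,
        pemt_levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
        noise_sd_cycles=0.0,
        seed=11,
    )
    return sd.generate_ct_table(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
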