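import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phyloprofiler import SpeciesCatalog, BinaryProfile, simulate_profiles

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def catalog6():
    return SpeciesCatalog(("s1", "s2", "s3", "s4", "s5", "s6"))


@pytest.fixture
def four_protein_profile(catalog6):
    """Two planted pairs with anti-correlated supports: links {A-B, C-D}."""
    values = np.array([
        [1, 1, 1, 1, 0, 0],  # A
        [1, 1, 1, 0, 0, 0],  # B
        [0, 0, 1, 1, 1, 1],  # C
        [0, 0, 0, 1, 1, 1],  # D
    ])
    return BinaryProfile(("A", "B", "C", "D"), catalog6, values)


@pytest.fixture
def clean_simulation():
    """Noise-free module simulation: 3 modules x 6 proteins, 60 species."""
    return simulate_profiles(n_modules=3, module_size=6, n_background=12,
                             m_species=60, flip_noise=0.0, seed=11)


def random_binary_profile(rng, n, m, prefix="p"):
    values = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(int)
    proteins = tuple(f"{prefix}{i}" for i in range(n))
    catalog = SpeciesCatalog(tuple(f"s{j}" for j in range(m)))
    return BinaryProfile(proteins, catalog, values)
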