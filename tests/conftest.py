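import numpy as np
import pytest

from gutcog.synthetic_cohort import (
    PlantedEffect,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structure cohort shared by read-only tests."""
    config = SimulationConfig(
        n_per_group={"HC": 20, "MCI": 10, "AD": 6},
        n_species=30,
        n_pathways=15,
        n_ko=24,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def planted_cohort():
    """Single-group cohort with planted species effects (MCI-like)."""
    from gutcog.synthetic_cohort import _species_clade

    planted = [
        PlantedEffect(feature_id=_species_clade(k), effect_size=6.0 * sign)
        for k, sign in zip(range(5), (1, -1, 1, -1, 1))
    ]
    config = SimulationConfig(
        n_per_group={"MCI": 40},
        n_species=40,
        n_pathways=10,
        n_ko=10,
        planted=planted,
        sigma_b=1.0,
        sigma_e=1.0,
        seed=23,
    )
    return simulate_cohort(config)


def clustered_noise(seed, m=30, ni=4, p=20):
    """Pure-noise clustered regression data."""
    rng = np.random.default_rng(seed)
    n = m * ni
    X = rng.normal(0, 1, (n, p))
    clusters = np.repeat([f"c{i}" for i in range(m)], ni)
    y = rng.normal(0, 1, n)
    return X, y, clusters
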