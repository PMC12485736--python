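import numpy as np
import pytest

from stfckit import SimulationConfig, generate_cohort, select_connected_region


@pytest.fixture(scope="session")
def null_cohort():
    """40-subject, 50-cluster cohort with no planted effect."""
    cfg = SimulationConfig(n_female=20, n_male=20, n_clusters=50, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """100-subject cohort with a strong planted effect on 5 connected clusters."""
    probe = generate_cohort(SimulationConfig(n_female=1, n_male=1, n_clusters=50, seed=202))
    region = select_connected_region(probe.graph, 5)
    ids = sorted(probe.feature_table.values.columns)
    cfg = SimulationConfig(
        n_female=50,
        n_male=50,
        n_clusters=50,
        effect_clusters=frozenset(ids.index(r) for r in region),
        effect_size=0.03,
        noise_sd=0.02,
        age_slope=-0.001,
        seed=202,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(4242)
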