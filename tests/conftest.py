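import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from morphdbn import preprocess_table
from morphdbn.simulate import GroupSpec, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact HC/SCZ cohort with a strong planted effect (d=1.5)."""
    cfg = SimulationConfig(
        hc=GroupSpec(60, 35.49, 11.08, 0.67),
        scz=GroupSpec(60, 37.12, 10.99, 0.66),
        fep=GroupSpec(0, 27.09, 7.97, 0.47),
        effect_size_d=1.5,
        seed=11,
    )
    table, truth = generate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def zscored_cohort(small_cohort):
    table, truth = small_cohort
    z, model = preprocess_table(table)
    return z, truth, model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
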