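import numpy as np
import pytest

from gxescan.config import SimulationConfig
from gxescan.prep import prepare_cohort
from gxescan.simulate import simulate_study


def small_simulation_config(**overrides) -> SimulationConfig:
    """A fast two-cohort config preserving the default effect structure."""
    kwargs = dict(
        n_subjects=(700, 750),
        n_variants=150,
        n_ld_partners=3,
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def single_cohort_config(n: int, **overrides) -> SimulationConfig:
    kwargs = dict(
        n_subjects=(n,),
        cohort_labels=("A",),
        drinker_fraction=(0.45,),
        age_mean_sd=((63.1, 9.9),),
        female_fraction=(0.64,),
        bmi_mean_sd=((23.4, 3.4),),
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_simulation_config())


@pytest.fixture(scope="session")
def prepared_small(small_study):
    return {
        label: prepare_cohort(table) for label, table in small_study.tables.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
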