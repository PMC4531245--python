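import numpy as np
import pytest

from rscleanbench.pipeline import analyze_cohort
from rscleanbench.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study cohort: 20 HC + 21 AD, 160 volumes, seed 0."""
    return generate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def default_battery(default_cohort):
    """Every subject run through all five cleanups and both FC methods."""
    cohort, truth = default_cohort
    analysis = analyze_cohort(cohort, truth)
    return cohort, truth, analysis


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural tests (6 subjects, short series)."""
    cfg = SimulationConfig(
        grid_shape=(20, 24, 18), n_volumes=48, n_hc=3, n_ad=3, n_templates=6, random_seed=7
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
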