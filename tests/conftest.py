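import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from treemap.impute import ImputationConfig, fit, impute
from treemap.plots import build_reference_table
from treemap.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic landscape shared across the suite."""
    cfg = SynthConfig(shape=(60, 60), n_plots=80, n_evg=6,
                      n_validation_plots=30, rng_seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_tables(small_synth):
    return build_reference_table(small_synth.plot_table, small_synth.tree_table,
                                 small_synth.stack)


@pytest.fixture(scope="session")
def small_model(small_tables):
    return fit(small_tables.reference, ImputationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_imputed(small_model, small_synth):
    return impute(small_model, small_synth.stack)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
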