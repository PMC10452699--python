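import numpy as np
import pytest

import mtdnet


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 subjects, 12 regions, 60 timepoints, strong group effect."""
    spec = mtdnet.default_spec(n_regions=12, n_modules=3)
    return mtdnet.generate_cohort(8, 8, 60, spec, effect=0.4, seed=11)


@pytest.fixture(scope="session")
def small_curves(small_cohort):
    nets = mtdnet.build_networks(small_cohort, window_length=40, step=10)
    grid = mtdnet.ThresholdGrid(0.01, 0.35, 0.01)
    return mtdnet.build_curves(nets, grid), grid


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
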