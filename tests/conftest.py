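import numpy as np
import pytest
from hypothesis import settings

import airdfc as a
from airdfc import exposure as expo

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    return a.NetworkLayout.small()


@pytest.fixture(scope="session")
def templates(small_layout):
    return a.build_state_templates(small_layout, seed=0)


@pytest.fixture(scope="session")
def world():
    return a.simulate_monitoring_world(n_days=365 * 6, seed=3)


@pytest.fixture(scope="session")
def ratio_series(world):
    annual = expo.annual_site_means(world.panel, world.reference_period)
    return expo.daily_ratio_series(world.panel, annual)


@pytest.fixture(scope="session")
def small_bundle(world, templates, ratio_series):
    """40-participant cohort with imaging, reused by read-only tests."""
    spec = a.CohortSpec(n_participants=40, seed=11, n_windows=40)
    return a.simulate_cohort(spec, world, templates, ratios=ratio_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
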