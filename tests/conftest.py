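import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dendrosim as ds

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_spec():
    return ds.FixtureSpec(n_sites=6, n_years_raw=80, seed=3)


@pytest.fixture(scope="session")
def raw_datasets(fixture_spec):
    return ds.make_raw_dataset(fixture_spec)


@pytest.fixture(scope="session")
def param_panel(raw_datasets):
    return ds.build_param_panel(raw_datasets, min_replication=15)


@pytest.fixture(scope="session")
def signal_panel(param_panel):
    return ds.simulate_signal_panel(param_panel, n_years=300, seed=1)


@pytest.fixture(scope="session")
def length_pool(fixture_spec):
    return ds.make_length_pool(fixture_spec, size=400, seed=5)


@pytest.fixture(scope="session")
def contrast_map(fixture_spec):
    return ds.ContrastMap.from_meta(fixture_spec.site_metadata())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
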