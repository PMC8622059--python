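import numpy as np
import pytest

import landsec as ls


@pytest.fixture(scope="session")
def registry():
    return ls.default_registry()


@pytest.fixture(scope="session")
def table1():
    return ls.load_fixture("table1_normalized")


@pytest.fixture(scope="session")
def table2():
    return ls.load_fixture("table2_weights")


@pytest.fixture(scope="session")
def table3():
    return ls.load_fixture("table3_results")


@pytest.fixture(scope="session")
def global_weights():
    return ls.fixture_global_weights()


@pytest.fixture(scope="session")
def main_weights():
    return ls.fixture_main_weights()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def raw_panel(registry):
    """Small deterministic raw panel (no noise) for IO / pipeline tests."""
    spec = ls.PanelSpec(
        years=range(2004, 2018),
        trends=ls.default_trends(registry, noise_sd=0.0),
        seed=0,
    )
    return ls.generate_panel(spec, registry)
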