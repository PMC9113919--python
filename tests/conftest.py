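import numpy as np
import pytest

from speedscale import build_bank, component_map, load_catalog


@pytest.fixture(scope="session")
def catalog():
    components, patterns = load_catalog()
    return components, patterns


@pytest.fixture(scope="session")
def components(catalog):
    return catalog[0]


@pytest.fixture(scope="session")
def patterns(catalog):
    return catalog[1]


@pytest.fixture(scope="session")
def cmap(components):
    return component_map(components)


@pytest.fixture(scope="session")
def pmap(patterns):
    return {p.id: p for p in patterns}


@pytest.fixture(scope="session")
def dg_catalog():
    components, patterns = load_catalog("DG")
    return component_map(components), {p.id: p for p in patterns}


@pytest.fixture(scope="session")
def bank():
    return build_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
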