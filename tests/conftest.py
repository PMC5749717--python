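import pytest

from mobius_assembly.fixtures import FixtureConfig, build_dummy_tu_parts, build_toolkit


@pytest.fixture(scope="session")
def cfg():
    return FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def toolkit(cfg):
    return build_toolkit(cfg)


@pytest.fixture(scope="session")
def parts16(cfg, toolkit):
    return build_dummy_tu_parts(cfg, 16, toolkit)
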