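import pytest

from pdlint import fixtures as fx


@pytest.fixture(scope="session")
def acsn_models():
    """The six ACSN-style fragments (canonical under its three map names,
    plus the stateless, SEF and detailed variants)."""
    return fx.build_acsn_collection()


@pytest.fixture(scope="session")
def panther_models():
    return fx.build_panther_collection()


@pytest.fixture(scope="session")
def all_preset_models():
    return {pid: fx.build_fixture(pid) for pid in fx.list_presets()}
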