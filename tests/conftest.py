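import numpy as np
import pytest

from isnp.background import BackgroundModel
from isnp.fixtures import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic input suite (seed 1), generated once per session."""
    d = tmp_path_factory.mktemp("fixture") / "fx"
    generate_fixture(FixtureConfig(seed=1), d)
    return d


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    import json
    with open(fixture_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform(order=0)
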