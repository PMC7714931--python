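import numpy as np
import pytest

from scat_twas.io import make_fixtures


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(seed=1, out_dir=out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
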