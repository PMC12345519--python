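import numpy as np
import pytest

from dusafnet import synth_corpus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_250_921)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """3 species x 4 clips, enough to exercise VAD/splitting/featurization."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = synth_corpus(3, 4, out, seed=7)
    return manifest
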