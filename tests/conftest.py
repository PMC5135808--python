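import numpy as np
import pytest

from regrecur.synthetic_data import make_fixture_bundle


@pytest.fixture(scope="session")
def tiny_manifest():
    """Small end-to-end bundle: 1 chrom x 100 kbp, 5 samples, 3 hotspots."""
    return make_fixture_bundle("tiny", seed=1)


@pytest.fixture(scope="session")
def default_manifest():
    """The 114-hotspot bundle mirroring the full-scale true-set regime."""
    return make_fixture_bundle("default", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
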