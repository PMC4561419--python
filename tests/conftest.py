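import numpy as np
import pytest

from seventm import motifs
from seventm.synth import (BundleSpec, make_ffa_like_trio, make_gpcr_sequence,
                           make_tm_bundle)


@pytest.fixture(scope="session")
def patterns():
    return motifs.default_patterns()


@pytest.fixture(scope="session")
def ffa_trio():
    return make_ffa_like_trio(seed=0)


@pytest.fixture(scope="session")
def gpcr_sequence():
    return make_gpcr_sequence(seed=1)


@pytest.fixture(scope="session")
def ca_bundle():
    return make_tm_bundle(BundleSpec(seed=0))


@pytest.fixture(scope="session")
def backbone_bundle():
    return make_tm_bundle(BundleSpec(seed=0, full_backbone=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
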