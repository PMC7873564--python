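import numpy as np
import pytest

from fcmurkit import domain_sequences as ds
from fcmurkit import synthetic_data as sd


@pytest.fixture(scope="session")
def human():
    return ds.human_domain()


@pytest.fixture(scope="session")
def mouse():
    return ds.mouse_domain()


@pytest.fixture(scope="session")
def human_mouse_alignment(human, mouse):
    return ds.align_global(human, mouse)


@pytest.fixture(scope="session")
def good_pose():
    return sd.gen_pentamer_complex(sd.PentamerParams(mode="good_pose"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
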