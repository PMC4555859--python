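import random

import pytest

from gwfold import (
    GroupScheme,
    derive_gw_matrix,
    get_benchmark,
    load_bm_matrix,
)


@pytest.fixture(scope="session")
def bm():
    return load_bm_matrix()


@pytest.fixture(scope="session")
def gw(bm):
    return derive_gw_matrix(bm, GroupScheme.default_six_group())


@pytest.fixture(scope="session")
def ctf():
    return get_benchmark("1CTF")


@pytest.fixture()
def rng():
    return random.Random(20150826)
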