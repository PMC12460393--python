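import numpy as np
import pytest

import fatedyn as fd


@pytest.fixture
def exp_growth():
    return fd.load_fixture("exp_growth")


@pytest.fixture
def aging_process():
    return fd.load_fixture("aging_growth_process")


@pytest.fixture
def aging_skew():
    return fd.load_fixture("aging_growth_skew")


@pytest.fixture
def fair_coin():
    return fd.BernoulliScheme(p=(0.5, 0.5), sided="two")


@pytest.fixture
def quadratic_halving():
    return fd.load_fixture("random_quadratic_halving")


@pytest.fixture
def affine_contraction():
    return fd.load_fixture("affine_random_contraction")


@pytest.fixture
def net2():
    return fd.load_fixture("net2_k1")
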