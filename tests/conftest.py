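import pytest

from ghnma import datasets

#: sampler settings small enough for unit tests but comfortably past the
#: convergence gate (2 chains x 2000 retained draws each)
SMALL_FIT = dict(chains=2, iterations=2500, burn_in=500)


@pytest.fixture(scope="session")
def base_trials():
    return datasets.load_base_case()


@pytest.fixture(scope="session")
def sa1_trials():
    return datasets.load_sa1()


@pytest.fixture(scope="session")
def sa2_trials():
    return datasets.load_sa2()
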