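import numpy as np
import pytest

from piezodyn import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def elastic_truth():
    return sd.ElasticTruth(d=1.4, dH=12.0, dS=25.0)


@pytest.fixture(scope="session")
def elastic_reference_set(elastic_truth):
    return sd.elastic_reference(elastic_truth)


@pytest.fixture(scope="session")
def qens_truth():
    return sd.QensTruth(tau=2.0, jump_len=1.2, gamma_loc=0.3)


@pytest.fixture(scope="session")
def qens_reference_set(qens_truth):
    return sd.qens_reference(qens_truth)



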