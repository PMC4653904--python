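import numpy as np
import pytest

from hthatlas.detect import detect_hth
from hthatlas.synth import SynthParams, make_hth_complex


@pytest.fixture(scope="session")
def base_complex():
    cplx, truth = make_hth_complex(SynthParams(seed=1))
    assessment = detect_hth(cplx)
    assert assessment.passed
    return cplx


@pytest.fixture(scope="session")
def base_truth():
    _, truth = make_hth_complex(SynthParams(seed=1))
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
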