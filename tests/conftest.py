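import numpy as np
import pytest

from memsctrnn.mems import MEMSParams, NetworkWeights


@pytest.fixture
def params() -> MEMSParams:
    return MEMSParams()


@pytest.fixture
def single_neuron() -> NetworkWeights:
    """One uncoupled neuron whose theta acts as the applied voltage."""
    return NetworkWeights(
        w_rec=np.zeros((1, 1)),
        w_in=np.zeros((1, 1)),
        theta=np.array([0.0]),
        w_out=np.zeros((2, 1)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
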