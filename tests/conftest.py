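import numpy as np
import pytest

from crispract.guide_design import GenomeSequence
from crispract.model_core import ModelSpec, TrainConfig, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_genome():
    """A random 3.2-kb linear sequence."""
    gen = np.random.default_rng(314)
    seq = "".join(np.array(list("ACGT"))[gen.integers(0, 4, size=3200)])
    return GenomeSequence(id="rand3200", sequence=seq, circular=False)


@pytest.fixture(scope="session")
def tiny_spec():
    """Very small architecture for fast unit tests."""
    return ModelSpec(
        input_len=28,
        shared_conv=(8, 5),
        cnn_branch=((8, 3),),
        cnn_pool=2,
        cnn_dense=8,
        bigru_units=6,
        rnn_dense=8,
        head_dense=(8,),
        dropout=0.1,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return build_model(tiny_spec, seed=7)


@pytest.fixture
def fast_cfg():
    return TrainConfig(epochs=2, batch_size=16, lr=1e-3, seed=0)
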