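import numpy as np
import pytest

from kegru import (
    MotifModel,
    SyntheticSpec,
    TrainConfig,
    generate_dataset,
    split_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """300 labeled 101-bp sequences with a planted consensus motif, split."""
    spec = SyntheticSpec(n_pos=150, n_neg=150, seed=101)
    ds, _ = generate_dataset(spec)
    return split_dataset(ds, (0.8, 0.1, 0.1), seed=102)


@pytest.fixture(scope="session")
def fast_config():
    """A desk-scale training configuration for functional tests."""
    return TrainConfig(units=8, optimizer="Adam", batch_size=64, epochs=2,
                       embedding_strategy="init_train", d=12, seed=103)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
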