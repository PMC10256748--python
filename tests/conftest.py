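import numpy as np
import pytest

import contiseg as cs
from contiseg.model import TrainConfig


@pytest.fixture(scope="session")
def tiny_pair():
    """Two small (16x16, 8-case) sites with swapped contrast — fast stand-in
    for the full benchmark in mechanics tests."""
    specs = cs.high_shift_pair(n_cases=8, image_shape=(16, 16))
    return cs.generate_sequence(specs, seed=11)


@pytest.fixture(scope="session")
def tiny_task(tiny_pair):
    return tiny_pair[0]


@pytest.fixture(scope="session")
def tiny_config():
    return TrainConfig(epochs=2, steps_per_epoch=5, seed=7)


@pytest.fixture(scope="session")
def trained_tiny(tiny_task, tiny_config):
    from contiseg.trainers import train_independent

    return train_independent(tiny_task, tiny_config)
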