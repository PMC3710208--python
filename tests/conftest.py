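import numpy as np
import pytest

from gelcorr import ExternalVariable, GelStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def noise_stack(rng):
    """6-sample 12x12 stack of pure i.i.d. noise, all pixels valid."""
    data = rng.random((6, 12, 12)) * 100
    return GelStack(data=data, valid=np.ones_like(data, dtype=bool),
                    sample_ids=[f"s{i}" for i in range(6)])


@pytest.fixture
def hours_var():
    return ExternalVariable("hours", [0.0, 2.0, 4.0, 6.0, 8.0])


def make_stack(data, valid=None, ids=None):
    data = np.asarray(data, dtype=float)
    if valid is None:
        valid = np.ones_like(data, dtype=bool)
    if ids is None:
        ids = [f"s{i}" for i in range(data.shape[0])]
    return GelStack(data=data, valid=valid, sample_ids=ids)
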