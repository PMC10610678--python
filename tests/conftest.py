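import numpy as np
import pytest

from dwimc import AlgorithmConfig, DwiStack


@pytest.fixture
def cfg():
    return AlgorithmConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20230146)


def make_stack(data, b_value=600.0, rep_labels=None):
    """Build a DwiStack from anything broadcastable to (z, i, y, x)."""
    data = np.asarray(data, dtype=float)
    while data.ndim < 4:
        data = data[None]
    return DwiStack(data=data, b_value=b_value, rep_labels=rep_labels)


@pytest.fixture
def voxel_series_stack():
    """Stack whose single voxel runs through a repetition series."""

    def _build(series):
        series = np.asarray(series, dtype=float)
        return make_stack(series.reshape(1, -1, 1, 1))

    return _build


@pytest.fixture
def random_stack(rng):
    """Small random stack: 1 slice, 5 reps, 4x4 voxels."""
    return make_stack(rng.uniform(10.0, 100.0, size=(1, 5, 4, 4)))
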