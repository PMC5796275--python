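import numpy as np
import pytest

from gaitseg.core import ImuRecording, SegmentLabelSet
from gaitseg.synthetic import (
    CLEAN_STRAIGHT,
    NOISELESS,
    StrideShapeParams,
    generate_cohort,
    generate_straight_walk,
)

FS = 102.4


@pytest.fixture(scope="session")
def clean_walk() -> tuple[ImuRecording, SegmentLabelSet]:
    """One low-variability 20-stride straight walk."""
    return generate_straight_walk(20, CLEAN_STRAIGHT, seed=11)


@pytest.fixture(scope="session")
def noiseless_walk() -> tuple[ImuRecording, SegmentLabelSet]:
    """Jitter- and noise-free walk: the construction oracle."""
    return generate_straight_walk(10, NOISELESS, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 2 feet of clean straight walks (8 strides each)."""
    return generate_cohort(4, preset="straight", seed=5, n_strides=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def recording_from_gz(gz: np.ndarray, fs: float = FS) -> ImuRecording:
    """Recording whose GZ channel is the given signal, other channels zero."""
    data = np.zeros((len(gz), 6))
    data[:, 5] = gz
    return ImuRecording(data=data, sample_rate_hz=fs)
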