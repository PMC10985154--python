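import numpy as np
import pytest

from stpmem import AssociativeMemory


@pytest.fixture(scope="session")
def example_modes():
    """The four 5-neuron learning modes of the worked example, bipolar form."""
    return [
        np.array([1, 1, -1, 1, 1], dtype=np.int8),
        np.array([1, -1, 1, -1, -1], dtype=np.int8),
        np.array([-1, 1, 1, -1, 1], dtype=np.int8),
        np.array([-1, -1, -1, 1, 1], dtype=np.int8),
    ]


@pytest.fixture(scope="session")
def example_indices():
    """delta_32 indices of the four example modes, in storage order."""
    return (5, 12, 19, 29)


@pytest.fixture()
def example_memory(example_modes):
    """Fresh memory over the four example modes with E_c = 2."""
    return AssociativeMemory(example_modes, bec=2)


@pytest.fixture(scope="session")
def example_probe():
    """The corrupted probe (-1,1,-1,1,1): bit 1 of mode X^1 flipped."""
    return np.array([-1, 1, -1, 1, 1], dtype=np.int8)
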