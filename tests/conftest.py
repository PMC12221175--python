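import numpy as np
import pytest

from ppigru import default_class_map, default_property_table
from ppigru.encoders import ProteinRecord

RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def props():
    return default_property_table()


@pytest.fixture(scope="session")
def cmap():
    return default_class_map()


@pytest.fixture(scope="session")
def random_proteins():
    """100 random canonical sequences of length 12..50, fixed seed."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(100):
        L = int(rng.integers(12, 51))
        out.append(ProteinRecord(f"R{i:03d}", "".join(rng.choice(RESIDUES, L))))
    return out


def random_sequence(rng, length):
    return "".join(rng.choice(RESIDUES, length))
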