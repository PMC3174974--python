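from pathlib import Path

import numpy as np
import pytest

from cisd import synthetic_data as syn

#: Directory for user-fetched reference data (deposited PDB entries and the
#: published supplementary sequence collections); see README.
EXTERNAL_DATA = Path(__file__).resolve().parent.parent / "data" / "external"


@pytest.fixture(scope="session")
def template():
    return syn.load_template()


@pytest.fixture(scope="session")
def symmetric_dimer():
    return syn.gen_dimer(syn.DimerParams(center_distance=15.0, symmetric=True))


@pytest.fixture(scope="session")
def sequences_500():
    """Large labelled sequence set shared by scanner/classifier tests."""
    return syn.gen_sequences(500, degeneracy_rate=0.2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
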