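import numpy as np
import pytest

from frscreen.chem_io import DescriptorTable, normalize_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table(rng):
    """12 compounds x 6 continuous descriptors, normalized."""
    values = rng.uniform(0.0, 1.0, size=(12, 6))
    t = DescriptorTable(
        [f"c{i}" for i in range(12)], [f"f{j}" for j in range(6)], values
    )
    return normalize_table(t)


def random_table(rng, n, f):
    values = rng.uniform(0.0, 1.0, size=(n, f))
    t = DescriptorTable([f"c{i}" for i in range(n)], [f"f{j}" for j in range(f)], values)
    return normalize_table(t)
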