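import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from torsearch.fixtures import make_chain_fixture, threefold_pes
from torsearch.molmodel import ZMatrix, ZMatrixRow


@pytest.fixture
def butane_zm() -> ZMatrix:
    """Minimal 4-atom chain with one target torsion."""
    rows = [
        ZMatrixRow("C"),
        ZMatrixRow("C", 0, 1.53),
        ZMatrixRow("C", 1, 1.53, 0, 112.0),
        ZMatrixRow("C", 2, 1.53, 1, 112.0, 0, "tor1"),
    ]
    return ZMatrix(rows, ["tor1"])


@pytest.fixture
def butanol_zm() -> ZMatrix:
    """Butanol-analogue chain: three target torsions."""
    return make_chain_fixture(3, "OH")


@pytest.fixture
def pes_t2():
    """3x3 grid of wells (two torsions) on a chain template."""
    return threefold_pes(2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
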