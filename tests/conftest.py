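import numpy as np
import pytest

from syncysim import MembraneParams
from syncysim.membrane import rheobase


@pytest.fixture(scope="session")
def baseline() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def baseline_rheobase(baseline) -> float:
    """Isolated-cell rheobase of the standard membrane (nA), shared across
    tests to avoid repeating the doubling search."""
    return rheobase(baseline)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210655)
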