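import numpy as np
import pytest

from boricflux.constants import DEFAULT_CONSTANTS
from boricflux.speciation import speciate
from boricflux.thermo import MembraneState


@pytest.fixture
def worked_state() -> MembraneState:
    """The oocyte worked example: 1.4 mM/pH 7.1 inside, 20 mM/pH 7.5 outside."""
    return MembraneState(
        inside=speciate(1.4e-3, 7.1),
        outside=speciate(20e-3, 7.5),
        delta_psi=0.0,
        temperature=DEFAULT_CONSTANTS.default_temperature,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221123)
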