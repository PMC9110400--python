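import numpy as np
import pytest

from coralmech import data
from coralmech.homogenize import (
    CrystalPhase,
    enforce_transverse_isotropy,
    self_consistent_stiffness,
)
from coralmech.strength import InterfaceStrength, polycrystal_strength


@pytest.fixture(scope="session")
def ti_crystal():
    """TI-enforced median experimental aragonite stiffness."""
    return enforce_transverse_isotropy(data.aragonite_median_stiffness())


@pytest.fixture(scope="session")
def phase(ti_crystal):
    """Baseline needle phase: aspect ratio 10, nano-porosity 3.9%."""
    return CrystalPhase(ti_crystal)


@pytest.fixture(scope="session")
def scs_state(phase):
    """Converged self-consistent polycrystal."""
    return self_consistent_stiffness(phase)


@pytest.fixture(scope="session")
def nacre_strengths(phase, scs_state):
    return polycrystal_strength(
        phase, scs_state.S_CS, InterfaceStrength(*data.NACRE_INTERFACE_MPA)
    )


@pytest.fixture(scope="session")
def calibrated_strengths(phase, scs_state):
    return polycrystal_strength(
        phase, scs_state.S_CS, InterfaceStrength(*data.MICROPILLAR_INTERFACE_MPA)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
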