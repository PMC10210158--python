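import numpy as np
import pytest

from allokin.scheme import Concentrations, DirectedRate, StateSpec, TransportCycleScheme
from allokin.thermo import ElementaryReaction, ModulatorBinding, ThermoContext


@pytest.fixture
def ctx():
    """Default thermodynamic context (293.15 K, kappa = 1)."""
    return ThermoContext()


@pytest.fixture
def symmetric_reaction():
    """The reference 2/2 s^-1 elementary reaction."""
    return ElementaryReaction(k_fw=2.0, k_bw=2.0)


@pytest.fixture
def product_selective_binding():
    """Modulator tenfold selective for the product state, 1 mM."""
    return ModulatorBinding(kd_reactant=1e-5, kd_product=1e-6, concentration=1e-3)


def _two_state(k_fw: float, k_bw: float) -> TransportCycleScheme:
    states = (
        StateSpec("A", "outward", False, False),
        StateSpec("B", "inward", False, False),
    )
    rates = (
        DirectedRate("A", "B", k_fw),
        DirectedRate("B", "A", k_bw),
    )
    return TransportCycleScheme(states, rates, Concentrations())


@pytest.fixture
def two_state_scheme():
    """Symmetric two-state toy network, 2 s^-1 each way."""
    return _two_state(2.0, 2.0)


@pytest.fixture
def moderate_cycle():
    """Biased 4-state cycle with O(1-100) rates; well-sampled by Gillespie."""
    states = tuple(
        StateSpec(n, "outward", False, False) for n in ("S1", "S2", "S3", "S4")
    )
    rates = (
        DirectedRate("S1", "S2", 50.0),
        DirectedRate("S2", "S3", 20.0),
        DirectedRate("S3", "S4", 80.0),
        DirectedRate("S4", "S1", 5.0),
        DirectedRate("S2", "S1", 10.0),
        DirectedRate("S3", "S2", 4.0),
        DirectedRate("S4", "S3", 16.0),
        DirectedRate("S1", "S4", 1.0),
    )
    return TransportCycleScheme(states, rates, Concentrations())
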