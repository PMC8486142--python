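import numpy as np
import pytest

from stenoflow import BLOOD, FlowWaveform, bc1, bc2_synthetic, make_fixture

#: BC1 mean inlet velocities per benchmark geometry (m/s); the sinusoid
#: amplitude is half the mean at both scales.
MEAN_U = {"G1": 0.02, "G2": 0.2, "G3": 0.02, "G4": 0.2}


@pytest.fixture(scope="session")
def fluid():
    return BLOOD


def waveform_for(name: str, bc: str, area: float) -> FlowWaveform:
    """Study inlet conditions for a benchmark geometry."""
    u = MEAN_U[name]
    if bc == "BC1":
        return bc1(u, u / 2.0, 1.0, area=area)
    if bc == "BC2":
        return bc2_synthetic(u, area=area)
    raise ValueError(bc)


def steady_waveform(u0: float, area: float) -> FlowWaveform:
    return FlowWaveform(
        period=1.0,
        area=area,
        velocity=lambda t: np.full_like(np.asarray(t, dtype=float), u0),
        velocity_derivative=lambda t: np.zeros_like(np.asarray(t, dtype=float)),
        label="steady",
    )


@pytest.fixture
def g1_half():
    return make_fixture("G1", 0.5)


@pytest.fixture
def g4_mid():
    return make_fixture("G4", 0.6)
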