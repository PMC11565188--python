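import numpy as np
import pytest

from smaddecode import default_smad_inputs
from smaddecode.fitting import CANONICAL_TIMES
from smaddecode.smad_input import SmadTrajectory


@pytest.fixture(scope="session")
def smad():
    """Default two-dose study design: low transient, high sustained."""
    return default_smad_inputs()


@pytest.fixture(scope="session")
def times():
    return np.asarray(CANONICAL_TIMES)


@pytest.fixture(scope="session")
def zero_smad():
    """Unstimulated input for both doses."""
    t = np.arange(0.0, 1441.0, 5.0)
    return {
        d: SmadTrajectory(d, t, np.zeros_like(t))
        for d in ("2.5pM", "100pM")
    }


def const_smad(level: float, label: str = "const") -> SmadTrajectory:
    return SmadTrajectory(label, [0.0, 1440.0], [level, level])
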