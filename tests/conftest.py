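import numpy as np
import pytest

from nebconvect import (
    BreathingSignal,
    ModelParams,
    PatternSpec,
    simulate,
    sinusoidal_waveform,
)


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    """Baseline circuit: 10 mL chamber, 1 mL dead space, 0.3 mL/min, 10 mL/s leak."""
    return ModelParams()


@pytest.fixture(scope="session")
def baseline_signal() -> "BreathingSignal":
    """Short baseline breathing pattern (10 mL, 70 bpm, duty 50%), 30 s."""
    return sinusoidal_waveform(PatternSpec(vt=10, rr=70, duty=0.5, duration=30, dt=0.01))


@pytest.fixture(scope="session")
def baseline_result(baseline_signal, baseline_params):
    return simulate(baseline_signal, baseline_params)


@pytest.fixture()
def zero_flow_signal():
    """Static signal (no breathing) for leak-only equilibrium checks."""
    n = 3001  # 30 s at 10 ms
    t = np.arange(n) * 0.01
    return BreathingSignal(t=t, V=np.zeros(n), phi=np.zeros(n), meta="zero flow")
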