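"""Breathing-signal generation, ingestion and their stated invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nebconvect import (
    PatternSpec,
    read_volume_trace,
    sinusoidal_waveform,
    variable_waveform,
    write_signal_csv,
)


@pytest.mark.parametrize(
    "vt,rr,duty",
    [(10.0, 70.0, 0.5), (2.0, 90.0, 0.3), (20.0, 50.0, 0.7), (5.0, 60.0, 0.5)],
)
def test_generated_waveform_amplitude_period_and_duty(vt, rr, duty):
    """Amplitude, period and inspiratory time match the pattern within 1%."""
    period = 60.0 / rr
    sig = sinusoidal_waveform(
        PatternSpec(vt=vt, rr=rr, duty=duty, duration=5 * period, dt=0.002)
    )
    amp = sig.V.max() - sig.V.min()
    assert amp == pytest.approx(vt, rel=0.01)
    # inspiratory time: first-breath samples at the peak volume
    first = sig.V[sig.t <= period + sig.dt / 2]
    ti = sig.t[np.argmax(first)]
    assert ti == pytest.approx(duty * period, abs=2 * sig.dt)
    # periodicity: one full breath later the volume repeats
    shift = int(round(period / sig.dt))
    n = sig.t.size - shift
    assert np.allclose(sig.V[:n], sig.V[shift : shift + n], atol=0.01 * vt)


def test_flow_integrates_to_zero_over_each_breath():
    """Volume returns to baseline: integral of phi over a whole breath is 0."""
    rr, vt = 60.0, 8.0
    sig = sinusoidal_waveform(PatternSpec(vt=vt, rr=rr, duty=0.3, duration=10, dt=0.005))
    per_breath = int(round(60.0 / rr / sig.dt))
    for k in range(5):
        seg = slice(k * per_breath, (k + 1) * per_breath + 1)
        # trapezoid error is O(dt^2) from the flow kink at the phase switch
        assert np.trapezoid(sig.phi[seg], sig.t[seg]) == pytest.approx(
            0.0, abs=1e-3 * vt
        )
        # and the volume itself closes exactly at breath boundaries
        assert sig.V[seg.start] == pytest.approx(0.0, abs=1e-9)
        assert sig.V[seg.stop - 1] == pytest.approx(0.0, abs=1e-9)


def test_flow_is_consistent_with_volume_derivative():
    """The analytic phi agrees with the sampled dV/dt away from phase corners."""
    sig = sinusoidal_waveform(PatternSpec(vt=10, rr=70, duty=0.5, duration=10, dt=0.01))
    assert sig.flow_consistency_error() < 0.01 * np.abs(sig.phi).max()


def test_duty_cycle_sets_time_to_peak_volume():
    """duty=0.3 at rr=60 puts the first V=vt crossing exactly at 0.3 s."""
    sig = sinusoidal_waveform(PatternSpec(vt=10, rr=60, duty=0.3, duration=5, dt=0.01))
    idx = np.argmax(sig.V >= 10.0 - 1e-9)
    assert sig.t[idx] == pytest.approx(0.3, abs=1e-9)


def test_half_cosine_baseline_is_pure_sinusoid_at_duty_half():
    """For duty 50% the two-arc construction collapses to (vt/2)(1-cos)."""
    vt, rr = 10.0, 70.0
    sig = sinusoidal_waveform(PatternSpec(vt=vt, rr=rr, duty=0.5, duration=5, dt=0.01))
    expected = 0.5 * vt * (1 - np.cos(2 * np.pi * sig.t / (60.0 / rr)))
    assert np.allclose(sig.V, expected, atol=1e-9)


@pytest.mark.parametrize("duty", [0.0, 1.0, -0.2, 1.5])
def test_invalid_duty_rejected(duty):
    with pytest.raises(ValueError):
        PatternSpec(vt=10, rr=70, duty=duty)


def test_undersampled_breath_rejected():
    """dt >= T_i/4 cannot resolve the inspiration and is refused."""
    with pytest.raises(ValueError, match="undersample"):
        sinusoidal_waveform(PatternSpec(vt=10, rr=70, duty=0.5, duration=10, dt=0.2))


def test_variable_with_collapsed_ranges_equals_sinusoid():
    """Degenerate vt/rr ranges reproduce the periodic generator sample-for-sample."""
    spec_var = PatternSpec(
        duty=0.5, duration=20, dt=0.01, seed=3, vt_range=(5, 5), rr_range=(70, 70)
    )
    spec_sin = PatternSpec(vt=5, rr=70, duty=0.5, duration=20, dt=0.01)
    var, sin = variable_waveform(spec_var), sinusoidal_waveform(spec_sin)
    assert np.array_equal(var.V, sin.V)
    assert np.array_equal(var.phi, sin.phi)


def test_variable_waveform_is_deterministic_for_fixed_seed():
    spec = PatternSpec(duty=0.3, duration=30, dt=0.01, seed=42)
    a, b = variable_waveform(spec), variable_waveform(spec)
    assert np.array_equal(a.V, b.V)
    # a different seed gives a different signal
    c = variable_waveform(PatternSpec(duty=0.3, duration=30, dt=0.01, seed=43))
    assert not np.array_equal(a.V, c.V)


def test_variable_breaths_respect_stated_ranges():
    """Every breath's amplitude lies in [2,20] mL and period in [60/90, 60/50] s."""
    sig = variable_waveform(
        PatternSpec(duty=0.3, duration=120, dt=0.005, seed=7,
                    vt_range=(2, 20), rr_range=(50, 90))
    )
    onsets = np.flatnonzero((sig.phi[1:] > 0) & (sig.phi[:-1] <= 0)) + 1
    assert onsets.size >= 80  # >= 50 bpm for 2 min, minus edge breaths
    for a, b in zip(onsets[:-1], onsets[1:]):
        period = sig.t[b] - sig.t[a]
        assert 60.0 / 90 - 2 * sig.dt <= period <= 60.0 / 50 + 2 * sig.dt
        amp = sig.V[a:b].max() - sig.V[a:b].min()
        assert 2.0 * 0.99 <= amp <= 20.0 * 1.01


@given(lo=st.floats(3, 18), width=st.floats(0, 2), seed=st.integers(0, 2**20))
@settings(max_examples=15, deadline=None)
def test_variable_amplitude_never_leaves_requested_interval(lo, width, seed):
    sig = variable_waveform(
        PatternSpec(duty=0.5, duration=15, dt=0.01, seed=seed,
                    vt_range=(lo, lo + width), rr_range=(50, 90))
    )
    assert sig.V.max() <= (lo + width) * 1.01
    assert sig.V.min() >= -1e-9


def test_inverted_range_rejected():
    with pytest.raises(ValueError):
        PatternSpec(duty=0.5, vt_range=(10, 5))


class TestVolumeTraceIO:
    def test_roundtrip_on_grid_is_identity(self, tmp_path):
        sig = sinusoidal_waveform(PatternSpec(vt=6, rr=60, duty=0.5, duration=5, dt=0.01))
        path = tmp_path / "trace.csv"
        write_signal_csv(sig, path)
        back = read_volume_trace(path, dt=0.01)
        assert np.allclose(back.V, sig.V, atol=1e-9)

    def test_derivative_matches_analytic_cosine(self, tmp_path):
        """phi recovered by central differences is O(dt^2)-close to the true one."""
        import pandas as pd

        t = np.arange(0, 4.0, 0.005)
        V = 5.0 * (1 - np.cos(2 * np.pi * t))
        path = tmp_path / "sine.csv"
        pd.DataFrame({"time_s": t, "volume_ml": V}).to_csv(path, index=False)
        sig = read_volume_trace(path, dt=0.01)
        true_phi = 10.0 * np.pi * np.sin(2 * np.pi * sig.t)
        assert np.allclose(sig.phi[1:-1], true_phi[1:-1], atol=0.1)

    def test_constant_volume_gives_zero_flow(self, tmp_path):
        path = tmp_path / "flat.csv"
        path.write_text("time_s,volume_ml\n" + "".join(f"{0.1 * i},4.0\n" for i in range(20)))
        sig = read_volume_trace(path, dt=0.05)
        assert np.allclose(sig.phi, 0.0, atol=1e-12)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,volume_ml\n0.0,1.0\n0.1,oops\n0.2,1.2\n")
        with pytest.raises(ValueError, match="line 3"):
            read_volume_trace(path, dt=0.05)

    def test_nonmonotone_time_rejected(self, tmp_path):
        path = tmp_path / "back.csv"
        path.write_text("time_s,volume_ml\n0.0,1.0\n0.2,1.1\n0.1,1.2\n")
        with pytest.raises(ValueError, match="decreases"):
            read_volume_trace(path, dt=0.05)

    def test_too_few_samples_rejected(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("time_s,volume_ml\n0.0,1.0\n0.1,1.1\n")
        with pytest.raises(ValueError, match="3 samples"):
            read_volume_trace(path, dt=0.05)
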