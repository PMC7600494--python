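"""Breathing waveform generation and ingestion.

All convective transport in the model is driven by the patient's lung
inflation flow.  This module produces that signal, either synthetically
(sinusoidal breaths at a fixed or randomly varying tidal volume and
respiratory rate) or from a recorded two-column time/volume trace.

Sign convention: ``phi = dV/dt`` with ``phi > 0`` during inspiration (lung
volume rising above the end-expiratory level) and ``phi < 0`` during
expiration.  Every downstream module consumes this signed flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreathingSignal",
    "PatternSpec",
    "sinusoidal_waveform",
    "variable_waveform",
    "read_volume_trace",
    "write_signal_csv",
]


@dataclass(frozen=True)
class BreathingSignal:
    """Uniformly sampled lung volume and flow time series.

    Attributes
    ----------
    t : np.ndarray
        Time grid in seconds, strictly increasing with constant step.
    V : np.ndarray
        Lung volume above the end-expiratory level, mL.
    phi : np.ndarray
        Lung inflation flow dV/dt, mL/s; positive during inspiration.
    meta : str
        Human-readable description of how the signal was produced.
    """

    t: np.ndarray
    V: np.ndarray
    phi: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        t, V, phi = (np.asarray(a, dtype=float) for a in (self.t, self.V, self.phi))
        if not (t.shape == V.shape == phi.shape) or t.ndim != 1:
            raise ValueError("t, V, phi must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("signal needs at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "phi", phi)

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Signal span in seconds."""
        return float(self.t[-1] - self.t[0])

    def flow_consistency_error(self) -> float:
        """Max interior difference between phi and the discrete dV/dt (mL/s).

        Generated signals carry the analytic derivative; this diagnostic
        bounds its departure from the sampled central-difference derivative
        on interior samples (O(dt^2) for smooth V, O(dt) at the two phase
        corners per breath).
        """
        dVdt = np.gradient(self.V, self.t)
        return float(np.max(np.abs(self.phi[1:-1] - dVdt[1:-1])))


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a synthetic breathing pattern.

    vt, rr and duty describe a single repeated breath; ``vt_range`` and
    ``rr_range`` replace vt/rr for breath-to-breath variable patterns.
    """

    vt: float = 10.0            # tidal volume, mL
    rr: float = 70.0            # respiratory rate, breaths/min
    duty: float = 0.5           # inspiratory fraction T_i/T_T
    duration: float = 300.0     # s
    dt: float = 0.01            # s
    seed: int = 0
    vt_range: tuple[float, float] | None = None   # mL, for variable patterns
    rr_range: tuple[float, float] | None = None   # bpm, for variable patterns

    def __post_init__(self) -> None:
        if self.vt <= 0:
            raise ValueError(f"tidal volume must be positive, got {self.vt}")
        if self.rr <= 0:
            raise ValueError(f"respiratory rate must be positive, got {self.rr}")
        if not 0.0 < self.duty < 1.0:
            raise ValueError(f"duty cycle must lie in (0, 1), got {self.duty}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        for name in ("vt_range", "rr_range"):
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if not (0 < lo <= hi):
                    raise ValueError(f"{name} must satisfy 0 < low <= high, got {rng}")


def _breath_schedule_signal(
    breaths: Sequence[tuple[float, float]], duty: float, duration: float, dt: float, meta: str
) -> BreathingSignal:
    """Evaluate a sequence of (vt, period) breaths on a uniform grid.

    Each breath rises from 0 to vt as a half cosine over T_i = duty * T and
    falls back over T_e = (1 - duty) * T, so volume is continuous everywhere
    and flow is continuous except at the two phase transitions.
    """
    vts = np.asarray([b[0] for b in breaths], dtype=float)
    periods = np.asarray([b[1] for b in breaths], dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    if starts[-1] < duration - 1e-9:
        raise ValueError("breath schedule does not cover the requested duration")

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(breaths) - 1)
    tau = t - starts[idx]
    vt = vts[idx]
    ti = duty * periods[idx]
    te = periods[idx] - ti

    insp = tau < ti
    V = np.empty(n)
    phi = np.empty(n)
    V[insp] = 0.5 * vt[insp] * (1.0 - np.cos(np.pi * tau[insp] / ti[insp]))
    phi[insp] = 0.5 * vt[insp] * np.pi / ti[insp] * np.sin(np.pi * tau[insp] / ti[insp])
    ex = ~insp
    x = (tau[ex] - ti[ex]) / te[ex]
    V[ex] = 0.5 * vt[ex] * (1.0 + np.cos(np.pi * x))
    phi[ex] = -0.5 * vt[ex] * np.pi / te[ex] * np.sin(np.pi * x)
    return BreathingSignal(t=t, V=V, phi=phi, meta=meta)


def _check_sampling(spec: PatternSpec, min_period: float) -> None:
    ti = spec.duty * min_period
    if spec.dt >= ti / 4.0:
        raise ValueError(
            f"dt={spec.dt} s undersamples the inspiration (T_i={ti:.3f} s); "
            "need dt < T_i/4"
        )


def sinusoidal_waveform(spec: PatternSpec) -> BreathingSignal:
    """Periodic breathing signal with period ``T = 60/rr`` seconds.

    For ``duty = 0.5`` this is the pure raised sinusoid
    ``V(t) = (vt/2) (1 - cos(2 pi t / T))``; for other duty cycles each
    breath is two half-cosine arcs of unequal duration so that the time
    from V=0 to the first V=vt is exactly ``duty * T``.
    """
    period = 60.0 / spec.rr
    if spec.duration < period:
        raise ValueError("duration must cover at least one breath")
    _check_sampling(spec, period)
    n_breaths = int(np.ceil(spec.duration / period)) + 1
    meta = f"sinusoidal vt={spec.vt} mL rr={spec.rr} bpm duty={spec.duty}"
    return _breath_schedule_signal(
        [(spec.vt, period)] * n_breaths, spec.duty, spec.duration, spec.dt, meta
    )


def variable_waveform(spec: PatternSpec) -> BreathingSignal:
    """Breath-to-breath variable signal emulating spontaneous neonatal breathing.

    Each breath's tidal volume and respiratory rate are drawn independently
    and uniformly from ``spec.vt_range`` and ``spec.rr_range`` (defaults
    2-20 mL and 50-90 bpm, the range observed in preterm newborns on
    noninvasive support); breath shape is the same two-arc cosine used by
    :func:`sinusoidal_waveform`.  Deterministic for a fixed seed.
    """
    vt_range = spec.vt_range if spec.vt_range is not None else (2.0, 20.0)
    rr_range = spec.rr_range if spec.rr_range is not None else (50.0, 90.0)
    _check_sampling(spec, 60.0 / rr_range[1])

    rng = np.random.default_rng(spec.seed)
    breaths: list[tuple[float, float]] = []
    total = 0.0
    while total < spec.duration + 1e-9:
        vt = rng.uniform(*vt_range)
        rr = rng.uniform(*rr_range)
        period = 60.0 / rr
        breaths.append((vt, period))
        total += period
    meta = (
        f"variable vt in {list(vt_range)} mL rr in {list(rr_range)} bpm "
        f"duty={spec.duty} seed={spec.seed}"
    )
    return _breath_schedule_signal(breaths, spec.duty, spec.duration, spec.dt, meta)


def read_volume_trace(path: str | Path, dt: float) -> BreathingSignal:
    """Read a recorded volume trace and resample it onto a uniform grid.

    The file is a two-column CSV with header ``time_s,volume_ml``.  Volume is
    linearly interpolated onto a grid with step ``dt``; flow is obtained by
    central differences (one-sided at the endpoints).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValueError(f"{path}: cannot parse volume trace: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, volume_ml)")
    tcol, vcol = df.columns[:2]
    t_raw = pd.to_numeric(df[tcol], errors="coerce").to_numpy(dtype=float)
    v_raw = pd.to_numeric(df[vcol], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(t_raw) | ~np.isfinite(v_raw))
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    if t_raw.size < 3:
        raise ValueError(f"{path}: need at least 3 samples, got {t_raw.size}")
    drops = np.flatnonzero(np.diff(t_raw) < 0)
    if drops.size:
        raise ValueError(f"{path}: time decreases at line {drops[0] + 3}")

    # collapse duplicate timestamps before interpolation
    t_u, first = np.unique(t_raw, return_index=True)
    v_u = v_raw[first]
    n = int(np.floor((t_u[-1] - t_u[0]) / dt)) + 1
    t = t_u[0] + np.arange(n) * dt
    V = np.interp(t, t_u, v_u)
    phi = np.gradient(V, dt)
    return BreathingSignal(t=t - t[0], V=V, phi=phi, meta=f"trace {path.name}")


def write_signal_csv(signal: BreathingSignal, path: str | Path) -> None:
    """Export a signal in the trace dialect plus a ``flow_ml_s`` column."""
    pd.DataFrame(
        {"time_s": signal.t, "volume_ml": signal.V, "flow_ml_s": signal.phi}
    ).to_csv(path, index=False)
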