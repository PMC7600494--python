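"""Explicit Euler integration of the compartment dynamics.

The integrator advances the aerosol amounts over a breathing signal with
the scheme the model was designed for (forward Euler, 10 ms default step)
plus a positivity-preserving flux limiter: the total amount removed from a
compartment within one step is capped at its current content, scaling all
of its outflows proportionally (upwind/finite-volume style).  This matters
because at v_uaw = 1 mL and peak neonatal flows near 90 mL/s the per-step
Courant number dt*phi/v_uaw approaches 1 and naive Euler can overshoot
negative.  Every removed amount is credited to exactly one sink or
compartment, so aerosol conservation is telescoping-exact up to float
roundoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, SimState
from .waveforms import BreathingSignal

__all__ = ["SimResult", "step", "simulate"]


def _advance(
    q_neb: float,
    q_uaw: float,
    phi: float,
    p: ModelParams,
) -> tuple[float, float, float, float, float, float, bool]:
    """One Euler step of the aerosol amounts.

    Returns (q_neb, q_uaw, d_delivered, d_leaked, d_vented, d_produced,
    limiter_active).  Phase is selected by the sign of ``phi``; phi = 0
    uses the static balance (production plus leak-driven washout).
    The limiter caps each compartment's total removal at its pre-step
    content; production and inflows are credited after removal so the cap
    never double-counts the current step's gains.
    """
    dt = p.dt
    delivered = leaked = vented = 0.0
    limited = False

    if phi > 0.0:
        c_neb = q_neb / p.v_neb
        out_pat = phi * c_neb * dt
        out_leak = p.leak * c_neb * dt
        total = out_pat + out_leak
        if total > q_neb and total > 0.0:
            scale = q_neb / total
            out_pat *= scale
            out_leak *= scale
            limited = True
        q_neb -= out_pat + out_leak
        leaked += out_leak
        if p.v_uaw > 0.0:
            out_lung = phi * (q_uaw / p.v_uaw) * dt
            if out_lung > q_uaw:
                out_lung = q_uaw
                limited = True
            q_uaw += out_pat - out_lung
            delivered += out_lung
        else:
            delivered += out_pat
    elif phi < 0.0:
        psi = -phi
        out_uaw = 0.0
        if p.v_uaw > 0.0:
            out_uaw = psi * (q_uaw / p.v_uaw) * dt
            if out_uaw > q_uaw:
                out_uaw = q_uaw
                limited = True
            q_uaw -= out_uaw
        c_neb = q_neb / p.v_neb
        vent_flow = psi - p.leak if psi > p.leak else 0.0
        out_vent = vent_flow * c_neb * dt
        out_leak = p.leak * c_neb * dt
        total = out_vent + out_leak
        if total > q_neb and total > 0.0:
            scale = q_neb / total
            out_vent *= scale
            out_leak *= scale
            limited = True
        q_neb += out_uaw - (out_vent + out_leak)
        vented += out_vent
        leaked += out_leak
    else:
        out_leak = p.leak * (q_neb / p.v_neb) * dt
        if out_leak > q_neb:
            out_leak = q_neb
            limited = True
        q_neb -= out_leak
        leaked += out_leak

    produced = p.d_neb * dt
    q_neb += produced
    return q_neb, q_uaw, delivered, leaked, vented, produced, limited


def step(state: SimState, phi: float, p: ModelParams) -> SimState:
    """Advance one integration step of length ``p.dt`` and return the new state."""
    state.validate()
    if not math.isfinite(phi):
        raise ValueError(f"flow must be finite, got {phi}")
    q_neb, q_uaw, d_del, d_leak, d_vent, d_prod, _ = _advance(
        state.q_neb, state.q_uaw, phi, p
    )
    return SimState(
        q_neb=q_neb,
        q_uaw=q_uaw,
        q_delivered=state.q_delivered + d_del,
        q_leaked=state.q_leaked + d_leak,
        q_vented=state.q_vented + d_vent,
        q_produced=state.q_produced + d_prod,
    )


@dataclass
class SimResult:
    """Full trajectory and sink bookkeeping of one simulation run."""

    params: ModelParams
    signal_meta: str
    t: np.ndarray
    q_neb_t: np.ndarray
    q_uaw_t: np.ndarray
    q_delivered: float
    q_leaked: float
    q_vented: float
    q_produced: float
    stabilization_time: float = math.nan
    n_limited: int = 0
    flux_log: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def conservation_residual(self) -> float:
        """|production - (contents + sinks)| at the final sample, mL."""
        return abs(
            self.q_produced
            - (
                self.q_neb_t[-1]
                + self.q_uaw_t[-1]
                + self.q_delivered
                + self.q_leaked
                + self.q_vented
            )
        )

    @property
    def conservation_residual_relative(self) -> float:
        return self.conservation_residual / self.q_produced if self.q_produced else 0.0

    def to_trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t, "q_neb_ml": self.q_neb_t, "q_uaw_ml": self.q_uaw_t}
        )

    def to_trajectory_csv(self, path) -> None:
        self.to_trajectory_frame().to_csv(path, index=False)


def _stabilization_time(t: np.ndarray, q_neb_t: np.ndarray, phi: np.ndarray) -> float:
    """First breath boundary where q_neb changes < 1% breath-to-breath.

    Breath boundaries are inspiration onsets (phi crossing from <= 0 to
    > 0).  Diagnostic only; the dose integral always covers the full run.
    """
    onset = np.flatnonzero((phi[1:] > 0) & (phi[:-1] <= 0)) + 1
    if onset.size < 3:
        return math.nan
    q = q_neb_t[onset]
    prev, cur = q[:-1], q[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(cur - prev) / np.where(cur > 0, cur, np.nan)
    stable = np.flatnonzero(rel < 0.01)
    if stable.size == 0:
        return math.nan
    return float(t[onset[stable[0] + 1]])


def simulate(
    signal: BreathingSignal, p: ModelParams, record_fluxes: bool = False
) -> SimResult:
    """Integrate the model over a breathing signal from aerosol-free start.

    All compartments start empty (nebulization begins at t = 0).  The
    signal's sampling step must equal the integration step ``p.dt``; the
    phase of each step is taken from the sign of phi at the step's left
    endpoint.  A warning is emitted if the positivity limiter was active
    on more than 0.1% of steps.
    """
    if abs(signal.dt - p.dt) > 1e-9 * max(signal.dt, p.dt):
        raise ValueError(
            f"signal dt={signal.dt} differs from integration dt={p.dt}; resample first"
        )
    n = signal.t.size
    phi = signal.phi
    q_neb_t = np.zeros(n)
    q_uaw_t = np.zeros(n)
    log = np.zeros((n - 1, 4)) if record_fluxes else None

    q_neb = q_uaw = 0.0
    delivered = leaked = vented = produced = 0.0
    n_limited = 0
    for i in range(n - 1):
        q_neb, q_uaw, d_del, d_leak, d_vent, d_prod, lim = _advance(
            q_neb, q_uaw, phi[i], p
        )
        if not (math.isfinite(q_neb) and math.isfinite(q_uaw)):
            raise FloatingPointError(f"state diverged at t={signal.t[i]:.3f} s")
        delivered += d_del
        leaked += d_leak
        vented += d_vent
        produced += d_prod
        n_limited += lim
        q_neb_t[i + 1] = q_neb
        q_uaw_t[i + 1] = q_uaw
        if log is not None:
            log[i] = (d_del, d_leak, d_vent, d_prod)

    if n_limited > 0.001 * (n - 1):
        warnings.warn(
            f"positivity limiter active on {n_limited}/{n - 1} steps; "
            "consider a smaller dt",
            RuntimeWarning,
            stacklevel=2,
        )
    flux_log = None
    if log is not None:
        flux_log = pd.DataFrame(
            log, columns=["delivered_ml", "leaked_ml", "vented_ml", "produced_ml"]
        )
    return SimResult(
        params=p,
        signal_meta=signal.meta,
        t=signal.t.copy(),
        q_neb_t=q_neb_t,
        q_uaw_t=q_uaw_t,
        q_delivered=delivered,
        q_leaked=leaked,
        q_vented=vented,
        q_produced=produced,
        stabilization_time=_stabilization_time(signal.t, q_neb_t, phi),
        n_limited=n_limited,
        flux_log=flux_log,
    )
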