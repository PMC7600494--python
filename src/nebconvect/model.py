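"""Compartment structure, parameters and per-phase aerosol flux equations.

The circuit is modelled as four well-mixed compartments in series:
mechanical ventilator, nebulizer chamber (volume ``v_neb``), the patient's
conducting airways (anatomical dead space, volume ``v_uaw``) and the lung.
Aerosol moves only by convection, carried by the patient's breathing flow
and by a constant interface leak; particles entering the lung are trapped
(they contribute to the delivered dose and are never exhaled), and aerosol
carried back to the Y-piece during expiration is washed out by the
ventilator bias flow.

Aerosol amounts are in mL of nebulized liquid, gas flows in mL/s, and all
compartments are assumed spatially uniform at every instant, so the aerosol
concentration leaving a compartment equals its bulk concentration q/V.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParams",
    "SimState",
    "InspirationFluxes",
    "ExpirationFluxes",
    "fluxes_inspiration",
    "fluxes_expiration",
    "flow_balance",
    "ml_per_min",
]

#: default aerosol production rate: 0.3 mL of liquid nebulized per minute
DEFAULT_D_NEB_ML_PER_MIN = 0.3


def ml_per_min(rate: float) -> float:
    """Convert a rate given in mL/min to the model's internal mL/s."""
    return rate / 60.0


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the ventilator-nebulizer-patient circuit.

    Parameters
    ----------
    v_neb : float
        Nebulizer chamber internal volume, mL (baseline 10 mL, a
        vibrating-mesh device at the Y-piece).
    v_uaw : float
        Upper-airway (anatomical dead space) volume, mL.  Zero removes the
        compartment structurally: the lung then exchanges flow directly
        with the nebulizer chamber.
    d_neb : float
        Aerosol production rate, mL of nebulized liquid per *second*.
        Use :func:`ml_per_min` for the usual mL/min figure.
    leak : float
        Constant gas flow escaping at the patient-interface connection,
        mL/s, carrying aerosol at chamber concentration to the ambient.
    dt : float
        Euler integration step, s.
    duration : float
        Simulated time, s.
    """

    v_neb: float = 10.0
    v_uaw: float = 1.0
    d_neb: float = field(default=DEFAULT_D_NEB_ML_PER_MIN / 60.0)
    leak: float = 10.0
    dt: float = 0.01
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.v_neb <= 0:
            raise ValueError(f"v_neb must be positive, got {self.v_neb}")
        if self.v_uaw < 0:
            raise ValueError(f"v_uaw must be >= 0, got {self.v_uaw}")
        if self.d_neb < 0:
            raise ValueError(f"d_neb must be >= 0, got {self.d_neb}")
        if self.leak < 0:
            raise ValueError(f"leak must be >= 0, got {self.leak}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with unit-suffixed keys."""
        return {
            "v_neb_ml": self.v_neb,
            "v_uaw_ml": self.v_uaw,
            "d_neb_ml_per_min": self.d_neb * 60.0,
            "leak_ml_per_s": self.leak,
            "dt_s": self.dt,
            "duration_s": self.duration,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        known = {
            "v_neb_ml": "v_neb",
            "v_uaw_ml": "v_uaw",
            "leak_ml_per_s": "leak",
            "dt_s": "dt",
            "duration_s": "duration",
        }
        kwargs: dict[str, float] = {}
        for key, value in data.items():
            if key == "d_neb_ml_per_min":
                kwargs["d_neb"] = ml_per_min(float(value))
            elif key == "d_neb_ml_per_s":
                kwargs["d_neb"] = float(value)
            elif key in known:
                kwargs[known[key]] = float(value)
            else:
                raise ValueError(f"unknown parameter key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a YAML or JSON mapping."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def with_(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


@dataclass
class SimState:
    """Instantaneous aerosol amounts (mL of liquid) plus cumulative sinks.

    ``q_delivered``, ``q_leaked`` and ``q_vented`` are the three terminal
    sinks (trapped in the lung, lost through the interface leak, washed out
    via the expiratory limb); ``q_produced`` is the running production
    integral, so conservation reads
    ``q_produced == q_neb + q_uaw + q_delivered + q_leaked + q_vented``.
    """

    q_neb: float = 0.0
    q_uaw: float = 0.0
    q_delivered: float = 0.0
    q_leaked: float = 0.0
    q_vented: float = 0.0
    q_produced: float = 0.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not value >= 0.0:  # also catches NaN
                raise ValueError(f"invalid state: {name} = {value}")

    @property
    def conservation_residual(self) -> float:
        return abs(
            self.q_produced
            - (self.q_neb + self.q_uaw + self.q_delivered + self.q_leaked + self.q_vented)
        )


@dataclass(frozen=True)
class InspirationFluxes:
    """Per-second aerosol fluxes while the patient inhales (phi > 0).

    ``neb_to_airway`` enters the dead-space compartment, or goes straight
    to the lung when the dead space is excluded (v_uaw = 0).  The
    ventilator supplies ``phi + leak`` of aerosol-free gas, so it
    contributes no aerosol term.
    """

    production: float     # mL/s into the chamber
    neb_to_airway: float  # phi * q_neb/v_neb
    airway_to_lung: float  # phi * q_uaw/v_uaw (0 if dead space excluded)
    neb_to_leak: float    # leak * q_neb/v_neb


@dataclass(frozen=True)
class ExpirationFluxes:
    """Per-second aerosol fluxes while the patient exhales (psi = -phi > 0).

    Dead-space gas (at concentration q_uaw/v_uaw) re-enters the chamber;
    the chamber loses aerosol through the leak and, when the exhaled flow
    exceeds the leak, through the expiratory limb at the net vent-ward
    flow ``max(psi - leak, 0)``.  No aerosol returns from the lung.
    """

    production: float
    airway_to_neb: float  # psi * q_uaw/v_uaw
    neb_to_vent: float    # max(psi - leak, 0) * q_neb/v_neb
    neb_to_leak: float    # leak * q_neb/v_neb


def fluxes_inspiration(state: SimState, phi: float, p: ModelParams) -> InspirationFluxes:
    """Instantaneous flux set for the inspiratory phase.

    ``phi`` is the lung inflation flow in mL/s and must be positive.
    """
    if not phi > 0:
        raise ValueError(f"inspiratory flow must be positive, got {phi}")
    c_neb = state.q_neb / p.v_neb
    to_lung = phi * (state.q_uaw / p.v_uaw) if p.v_uaw > 0 else 0.0
    return InspirationFluxes(
        production=p.d_neb,
        neb_to_airway=phi * c_neb,
        airway_to_lung=to_lung,
        neb_to_leak=p.leak * c_neb,
    )


def fluxes_expiration(state: SimState, psi: float, p: ModelParams) -> ExpirationFluxes:
    """Instantaneous flux set for the expiratory phase.

    ``psi`` is the exhaled flow magnitude in mL/s and must be positive.
    When ``psi < leak`` the deficit is made up by fresh (aerosol-free)
    ventilator gas, so no aerosol reaches the expiratory limb.
    """
    if not psi > 0:
        raise ValueError(f"exhaled flow must be positive, got {psi}")
    c_neb = state.q_neb / p.v_neb
    from_uaw = psi * (state.q_uaw / p.v_uaw) if p.v_uaw > 0 else 0.0
    vent_flow = max(psi - p.leak, 0.0)
    return ExpirationFluxes(
        production=p.d_neb,
        airway_to_neb=from_uaw,
        neb_to_vent=vent_flow * c_neb,
        neb_to_leak=p.leak * c_neb,
    )


def flow_balance(phi_signed: float, leak: float) -> float:
    """Ventilator gas flow closing the gas balance at the nebulizer node.

    Returns the signed fresh-gas supply from the ventilator limb, mL/s:
    positive means the ventilator feeds gas toward the patient/leak,
    negative means exhaled gas is carried away into the expiratory limb.
    With a constant leak the balance is simply ``phi + leak``: during
    inspiration the ventilator supplies patient flow plus leak; during
    expiration it removes ``max(|phi| - leak, 0)`` and, if the exhaled
    flow is smaller than the leak, supplies the ``leak - |phi|`` deficit.
    """
    return phi_signed + leak
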