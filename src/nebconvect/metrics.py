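"""Scalar outcomes of a simulation run.

The headline quantity is the percentage of the nebulized drug delivered to
the lung, %D_DL = 100 * (integral of the delivered-dose rate) / (integral
of the production rate), both taken over the full run including the
start-up transient.  Because the model is linear in the aerosol amount,
%D_DL is independent of the production rate itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .simulation import SimResult

__all__ = ["RunMetrics", "percent_ddl", "mean_chamber_amount", "sink_breakdown"]

#: default trailing window (s) for the post-equilibrium chamber average
DEFAULT_MEAN_WINDOW = 60.0


@dataclass(frozen=True)
class RunMetrics:
    """Percentage fate of the nebulized drug plus chamber-load diagnostics.

    The four percentage shares use total production as the common
    denominator and sum to 100 by aerosol conservation; ``percent_residual``
    is aerosol still suspended in the circuit (chamber + dead space) when
    the run ends.
    """

    percent_ddl: float
    percent_leaked: float
    percent_vented: float
    percent_residual: float
    mean_q_neb: float          # time-averaged chamber load over the trailing window, mL
    stabilization_time: float  # s, NaN if periodic steady state was not detected

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def percent_ddl(result: SimResult) -> float:
    """Percentage of the total nebulized drug trapped in the lung."""
    if result.q_produced <= 0:
        raise ValueError("%D_DL undefined: no aerosol was produced")
    return 100.0 * result.q_delivered / result.q_produced


def mean_chamber_amount(result: SimResult, window: float = DEFAULT_MEAN_WINDOW) -> float:
    """Time average of the chamber aerosol load over the trailing window (mL).

    The default final-minute window reports the post-equilibrium value:
    the chamber settles into a periodic oscillation after a few breaths,
    so the trailing average is insensitive to the start-up transient.
    """
    duration = result.t[-1] - result.t[0]
    if window > duration + 1e-9:
        raise ValueError(f"window {window} s exceeds run duration {duration} s")
    mask = result.t >= result.t[-1] - window
    return float(np.mean(result.q_neb_t[mask]))


def sink_breakdown(result: SimResult, window: float = DEFAULT_MEAN_WINDOW) -> RunMetrics:
    """Full accounting of where the nebulized drug went."""
    produced = result.q_produced
    if produced <= 0:
        raise ValueError("sink breakdown undefined: no aerosol was produced")
    residual = result.q_neb_t[-1] + result.q_uaw_t[-1]
    return RunMetrics(
        percent_ddl=100.0 * result.q_delivered / produced,
        percent_leaked=100.0 * result.q_leaked / produced,
        percent_vented=100.0 * result.q_vented / produced,
        percent_residual=100.0 * residual / produced,
        mean_q_neb=mean_chamber_amount(result, window),
        stabilization_time=result.stabilization_time,
    )
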