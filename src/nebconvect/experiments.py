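"""Preset simulation scenarios, parameter sweeps and tidy result tables.

Eight standard scenarios probe one influence at a time: the baseline run,
the tidal-volume/leak grid with the dead space excluded or included, dead
spaces of 0.5/1.5 mL, chamber volumes of 3/18 mL, respiratory rates of
50/90 bpm, duty cycles of 30%/70%, and a set of seeded variable breathing
patterns emulating spontaneously breathing preterm newborns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import mean_chamber_amount, percent_ddl
from .model import ModelParams
from .simulation import simulate
from .waveforms import PatternSpec, sinusoidal_waveform, variable_waveform

__all__ = [
    "Combo",
    "preset",
    "run_sweep",
    "baby_scenarios",
    "SWEEP_COLUMNS",
    "LEAK_LEVELS",
    "VT_GRID",
    "SMALL_BABY_VT",
    "LARGE_BABY_VT",
]

logger = logging.getLogger(__name__)

#: leak levels explored in every grid scenario, mL/s
LEAK_LEVELS: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
#: default tidal-volume grid, mL (2-20 in 1 mL steps)
VT_GRID: tuple[float, ...] = tuple(float(v) for v in range(2, 21))

# Representative newborns spanning the 26-33 week gestational-age
# population (body weights 0.7 and 2.0 kg at a ~6 mL/kg tidal volume).
SMALL_BABY_VT = 5.0   # mL
LARGE_BABY_VT = 14.0  # mL

SWEEP_COLUMNS = [
    "sim_id",
    "arm",
    "vt_ml",
    "rr_bpm",
    "duty",
    "v_neb_ml",
    "v_uaw_ml",
    "leak_ml_per_s",
    "seed",
    "percent_ddl",
    "mean_q_neb_ml",
    "conservation_residual_rel",
]


@dataclass(frozen=True)
class Combo:
    """One fully specified run: breathing pattern plus circuit parameters."""

    sim_id: int
    arm: str = ""
    kind: str = "sinusoidal"   # or "variable"
    vt: float = 10.0
    rr: float = 70.0
    duty: float = 0.5
    v_neb: float = 10.0
    v_uaw: float = 1.0
    leak: float = 10.0
    seed: int | None = None    # only for variable patterns
    vt_range: tuple[float, float] = (2.0, 20.0)
    rr_range: tuple[float, float] = (50.0, 90.0)

    def pattern_spec(self, duration: float, dt: float) -> PatternSpec:
        if self.kind == "variable":
            return PatternSpec(
                duty=self.duty,
                duration=duration,
                dt=dt,
                seed=0 if self.seed is None else self.seed,
                vt_range=self.vt_range,
                rr_range=self.rr_range,
            )
        return PatternSpec(
            vt=self.vt, rr=self.rr, duty=self.duty, duration=duration, dt=dt
        )

    def model_params(self, duration: float, dt: float) -> ModelParams:
        return ModelParams(
            v_neb=self.v_neb, v_uaw=self.v_uaw, leak=self.leak, dt=dt, duration=duration
        )


def _grid(
    sim_id: int,
    vt_grid: tuple[float, ...],
    leaks: tuple[float, ...],
    arm: str = "",
    **overrides,
) -> list[Combo]:
    return [
        Combo(sim_id=sim_id, arm=arm, vt=vt, leak=leak, **overrides)
        for vt in vt_grid
        for leak in leaks
    ]


def preset(
    sim_id: int,
    vt_grid: tuple[float, ...] = VT_GRID,
    leaks: tuple[float, ...] = LEAK_LEVELS,
    n_traces: int = 10,
    seed: int = 0,
) -> list[Combo]:
    """Expand one of the eight standard scenarios into run combinations.

    1. baseline: single run at vt 10 mL, rr 70 bpm, duty 50%, v_neb 10 mL,
       v_uaw 1 mL, leak 10 mL/s;
    2. vt/leak grid with the dead space excluded (v_uaw = 0);
    3. same grid with v_uaw = 1 mL;
    4. dead-space arms 0.5 mL (a) and 1.5 mL (b);
    5. chamber-volume arms 3 mL (a) and 18 mL (b);
    6. respiratory-rate arms 50 (a) and 90 (b) bpm;
    7. duty-cycle arms 30% (a) and 70% (b);
    8. ``n_traces`` seeded variable breathing patterns (vt 2-20 mL,
       rr 50-90 bpm, duty 30%) crossed with every leak level.
    """
    if sim_id == 1:
        return [Combo(sim_id=1)]
    if sim_id == 2:
        return _grid(2, vt_grid, leaks, v_uaw=0.0)
    if sim_id == 3:
        return _grid(3, vt_grid, leaks)
    if sim_id == 4:
        return _grid(4, vt_grid, leaks, arm="a", v_uaw=0.5) + _grid(
            4, vt_grid, leaks, arm="b", v_uaw=1.5
        )
    if sim_id == 5:
        return _grid(5, vt_grid, leaks, arm="a", v_neb=3.0) + _grid(
            5, vt_grid, leaks, arm="b", v_neb=18.0
        )
    if sim_id == 6:
        return _grid(6, vt_grid, leaks, arm="a", rr=50.0) + _grid(
            6, vt_grid, leaks, arm="b", rr=90.0
        )
    if sim_id == 7:
        return _grid(7, vt_grid, leaks, arm="a", duty=0.3) + _grid(
            7, vt_grid, leaks, arm="b", duty=0.7
        )
    if sim_id == 8:
        trace_seeds = np.random.SeedSequence(seed).generate_state(n_traces) % (2**31)
        return [
            Combo(
                sim_id=8,
                arm=f"trace{k}",
                kind="variable",
                duty=0.3,
                leak=leak,
                seed=int(s),
            )
            for k, s in enumerate(trace_seeds)
            for leak in leaks
        ]
    raise ValueError(f"unknown simulation id {sim_id}; expected 1..8")


def run_sweep(
    combos: list[Combo],
    duration: float = 300.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Run every combination and collect a tidy long-format results table.

    Identical signals (same pattern within a scenario, different leaks)
    are generated once and reused.  Rows appear in the order of ``combos``.
    """
    if not combos:
        raise ValueError("no combinations to run")
    rows = []
    signal_cache: dict[tuple, object] = {}
    for k, combo in enumerate(combos):
        spec = combo.pattern_spec(duration, dt)
        key = (combo.kind, spec.vt, spec.rr, spec.duty, spec.seed, spec.vt_range, spec.rr_range)
        signal = signal_cache.get(key)
        if signal is None:
            generator = variable_waveform if combo.kind == "variable" else sinusoidal_waveform
            signal = generator(spec)
            signal_cache[key] = signal
        try:
            result = simulate(signal, combo.model_params(duration, dt))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for {combo}") from exc
        rows.append(
            {
                "sim_id": combo.sim_id,
                "arm": combo.arm,
                "vt_ml": combo.vt if combo.kind == "sinusoidal" else np.nan,
                "rr_bpm": combo.rr if combo.kind == "sinusoidal" else np.nan,
                "duty": combo.duty,
                "v_neb_ml": combo.v_neb,
                "v_uaw_ml": combo.v_uaw,
                "leak_ml_per_s": combo.leak,
                "seed": combo.seed,
                "percent_ddl": percent_ddl(result),
                "mean_q_neb_ml": mean_chamber_amount(
                    result, window=min(60.0, duration / 2)
                ),
                "conservation_residual_rel": result.conservation_residual_relative,
            }
        )
        logger.info("run %d/%d done (%s)", k + 1, len(combos), combo)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def baby_scenarios(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize the two representative newborns across all leak levels.

    Extracts the tidal volumes of the smallest (0.7 kg, ~5 mL) and largest
    (2.0 kg, ~14 mL) babies of the target population from a sweep table and
    reports min/max %D_DL per scenario over the leak levels present.
    """
    out = []
    for label, vt in (("small_baby", SMALL_BABY_VT), ("large_baby", LARGE_BABY_VT)):
        rows = table[table["vt_ml"] == vt]
        if rows.empty:
            raise ValueError(f"sweep table has no rows at vt = {vt} mL ({label})")
        out.append(
            {
                "scenario": label,
                "vt_ml": vt,
                "n_leaks": rows["leak_ml_per_s"].nunique(),
                "min_percent_ddl": rows["percent_ddl"].min(),
                "max_percent_ddl": rows["percent_ddl"].max(),
            }
        )
    return pd.DataFrame(out)
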