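# Methods

## Model and assumptions

`nebconvect` treats the ventilation circuit as four well-mixed compartments:
a mechanical ventilator (infinite source/sink of fresh gas), a nebulizer
chamber of volume `v_neb` between the Y-piece and the patient interface, the
patient's conducting airways (`v_uaw`, the anatomical dead space), and the
lung. The model isolates *convective* transport:

1. aerosol moves only as carried by gas flow — no diffusion;
2. no deposition anywhere outside the lung (no impaction, coalescence,
   sedimentation, particle-size effects);
3. all aerosol entering the lung during inspiration is trapped and none is
   exhaled back;
4. the nebulizer injects aerosol into its chamber at a constant rate
   `d_neb`, independent of flow and pressure;
5. aerosol reaching the Y-piece during exhalation is entirely washed out by
   the circuit bias flow (the ventilator limb is an absorbing sink);
6. the interface leak is a constant flow, independent of the breathing
   phase — the nCPAP case. Pressure-synchronous leaks (nIPPV) are out of
   scope.

Because volumes are fixed and gas is incompressible here, the gas balance at
the nebulizer node is `V̇_vent = V̇_patient + V̇_leaks` (signed, positive
toward the patient); the nebulized liquid volume itself is negligible in the
gas budget. The model is linear in aerosol amount, so every percentage
outcome is independent of `d_neb`; the default rate only scales the absolute
trajectories.

### Sign conventions and the expiratory closure

All flows are derived from a single signed lung-inflation flow
`phi = dV/dt` (positive during inspiration). During expiration the exhaled
flow `psi = −phi` first refills the chamber with dead-space gas at
concentration `q_uaw/v_uaw` (and with aerosol-free lung gas once the dead
space is exhausted); the chamber loses aerosol through the leak at
`leak · q_neb/v_neb` and toward the expiratory limb at
`W · q_neb/v_neb` with `W = max(psi − leak, 0)`. The `max(·, 0)` closure is
a deliberate design choice for the regime `psi < leak`, which the plain
equations leave open: the gas deficit must come from somewhere, and the
ventilator limb is continuously flushed with fresh aerosol-free gas, so a
weak exhalation feeds the leak entirely and nothing reaches the vent. This
regime genuinely occurs (e.g. tidal volume 5 mL at 70 bpm never exceeds
18 mL/s of exhaled flow, so a 20 mL/s leak captures everything).

### Dead-space exclusion

`v_uaw = 0` removes the compartment *structurally* — the lung exchanges flow
directly with the chamber — rather than taking a 1/v_uaw limit. This matches
the scenario used to isolate the dead-space effect and avoids a stiff
artificial compartment.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| `v_neb` | nebulizer chamber internal volume | mL | 10 | a vibrating-mesh device for neonatal use |
| `v_uaw` | anatomical dead space | mL | 1 | extrapolated neonatal airway anatomy |
| `d_neb` | aerosol production rate | mL/s | 0.005 (= 0.3 mL/min) | typical vibrating-mesh output; constructors convert mL/min explicitly, never silently |
| `leak` | interface leak flow | mL/s | 10 | mid-range of clinically observed nCPAP leaks (grids use 0/5/10/20) |
| `dt` | Euler step | s | 0.01 | resolves the fastest breath (T_i ≥ 0.2 s) with ≥ 20 samples |
| `duration` | simulated time | s | 300 | long enough for every configuration to reach its periodic steady state |
| `vt`, `rr`, `duty` | tidal volume, rate, inspiratory fraction | mL, bpm, – | 10, 70, 0.5 | baseline preterm pattern; grids span 2–20 mL, 50–90 bpm, 30–70% |

## Breathing waveforms

Generated breaths are half-cosine arcs: volume rises 0 → vt over
`T_i = duty · T` and falls back over `T_e = (1 − duty) · T`. For duty = 50%
this collapses exactly to the raised sinusoid `(vt/2)(1 − cos 2πt/T)`. The
two-arc shape is the simplest curve consistent with that baseline and an
exact duty cycle: volume is continuous everywhere, flow is continuous except
for a slope kink at the two phase switches. Flow is carried analytically on
the same grid as volume.

The variable-pattern generator emulates the natural breath-to-breath
variability of preterm newborns on noninvasive support: each breath draws
its tidal volume and rate independently and uniformly from stated ranges
(defaults 2–20 mL, 50–90 bpm, duty 30%). Only ranges are known for the real
population, so the uniform i.i.d. draw is a design decision, with two
consequences worth stating plainly. First, over a 5-minute run the
per-breath draws average out, so a synthetic "patient" behaves like a
mid-range breather. Second, every synthetic patient shares the same breath
distribution, whereas real patients differ persistently in their mean tidal
volume. The between-patient spread of %D_DL computed from these traces is
therefore much narrower than the spread recorded with real neonatal volume
traces, and tests on it are qualitative only (the spread widens with leak);
they do not show that the model reproduces real patient-to-patient
variability. Recorded traces can be fed in directly as `time_s,volume_ml`
CSV files (linear resampling, central-difference flow).

## Numerical scheme

Explicit Euler with the step the model was designed around (10 ms), with
one addition: a **positivity-preserving flux limiter**. At `v_uaw = 1` mL
and peak flows approaching 150 mL/s (high rate, low duty), the per-step
Courant number `dt·phi/v_uaw` exceeds 1 and naive Euler would drive the
dead-space content negative. The limiter caps the total amount removed from
a compartment in one step at its pre-step content, scaling all of its
outflows proportionally; production and inflows are credited after removal.
Where the limiter is inactive the scheme *is* forward Euler on the model
equations (asserted in tests); its activations are counted per run and a
warning is raised if they exceed 0.1% of steps, so its influence can be
audited. Every removed amount is credited to exactly one sink or
compartment, making aerosol conservation
(`q_produced = q_neb + q_uaw + q_delivered + q_leaked + q_vented`)
telescoping-exact up to float roundoff; observed residuals are ~10⁻¹³
relative over 30 000 steps, and every result object exposes the residual.

Other numerical choices:

- phase is selected per step from the sign of `phi` at the step's left
  endpoint; `phi = 0` steps use the static balance (production plus
  leak-driven washout), whose discrete fixed point is exactly
  `q_neb = d_neb · v_neb / leak`;
- all compartments start empty — nebulization begins at t = 0 — and %D_DL
  integrates the full run *including* the start-up transient, as a literal
  ratio of the delivered and produced integrals; no transient-exclusion
  rule is applied;
- the steady-state detector (first breath whose start-of-breath chamber
  load changes < 1% from the previous breath) is diagnostic only and never
  truncates the dose integral;
- the reported mean chamber load averages the final 60 s of the run. The
  averaging window behind the equilibrium chamber-load curves is not
  pinned down anywhere, so the final minute — comfortably post-equilibrium
  in every scenario — is this package's choice;
- halving dt changes baseline %D_DL by far less than 0.5 percentage points
  (asserted in tests), so the 10 ms step is converged for the reported
  precision.

## Standard scenarios

`experiments.preset(1..8)` encodes the eight standard runs: (1) baseline;
(2) vt × leak grid with the dead space excluded; (3) the same with
`v_uaw = 1` mL; (4) dead-space arms 0.5/1.5 mL; (5) chamber arms 3/18 mL;
(6) rate arms 50/90 bpm; (7) duty arms 30%/70%; (8) ten seeded variable
traces × leaks. The tidal-volume grid runs 2–20 mL in 1 mL steps (the grid
step is a package choice; reported figures only use named volumes). The two
representative newborns — 0.7 and 2.0 kg, the weight limits of the 26–33
week population — are carried as tidal volumes of 5 and 14 mL. Note that a
strict 6 mL/kg conversion would give 4.2 and 12 mL; the 5/14 mL figures are
the values conventionally quoted for these scenarios and are used as-is
rather than recomputed from weight.

Scenario 8 stands in for real recorded traces, which are not distributed;
its results are qualitative (see the waveform section above).

## Known limitations

- No deposition physics at all: the computed %D_DL is the *convective
  ceiling* on lung dose, not a deposition prediction. Multiplying it by an
  in-vitro deposition fraction is a back-of-envelope extrapolation left to
  the reader, not something the package computes.
- Constant leak only; pressure-varying leaks (nIPPV) would need a
  leak-vs-phase model.
- Well-mixed compartments ignore axial concentration gradients in the
  chamber; at high flows this overestimates mixing.
- The variable-breathing generator does not emulate apneas, sighs, or
  per-patient identity (see above).
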