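# Methods

## Model

Flow through the D-Lite constriction is modeled by the Venturi relation
Q = Cd·Ac·√(2ΔP/ρ) and its algebraic inverse ΔP = Q²ρ/(2Cd²Ac²). Both are
computed in SI (Pa, m², kg/m³, m³/s) with boundary conversions only
(1 m³/s = 60000 L/min; 1 cmH₂O = 98.0665 Pa for display). Flow is
bidirectional; negative differential pressure maps to negative (expiratory)
flow by odd extension, since the method states a single calibration protocol
for both directions. The estimator therefore searches the table on |DPS| and
re-applies the sign — the positive calibration branch is mirrored for
expiration, a documented assumption.

Gas density uses the ideal-gas mixture model ρ = P_abs·M_mix/(R·T), where
M_mix is the volume-weighted molar mass of a two-component blend of air
(21% O₂) and pure oxygen. The FiO₂ → blend mapping is the linear mixing
model %V_O2 = (FiO₂ − 21)/(100 − 21)·100, the unique two-component blend
consistent with the pure-air and pure-O₂ endpoints. Humidity, CO₂ content
and non-ideal behaviour are out of scope.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| Cd | 0.7 | – | the method's fixed design constant; residual Cd variation is absorbed by the table |
| Ac | 58 | mm² | total cross-section of the three spirometer ports |
| m_air, m_O2 | 28.97, 31.999 | g/mol | standard handbook values; overridable via config |
| R | 8.314 | J/(mol·K) | universal gas constant |
| Δt | 5 | ms | nominal flow/volume sampling interval; irregular timestamps accepted |
| calibration grid | 1–40 by 1, 45–80 by 5 | L/min | dense where trigger flows live, coarse to the saturation point; 48 rows |
| DPS merge tolerance | 0.01 | Pa | sensor offset-stability scale; readings closer than this are averaged into one row |
| breath hysteresis | 2 L/min for ≥ 50 ms | – | inspiratory-onset detection threshold, inside the 1–20 L/min trigger-flow band; tunable |

Every constant is a named default (config keys `gas.*`, `venturi.*`,
`density.airway_pressure_mode`, `sampling.dt_s`, `breaths.*`), never a code
literal.

## Lookup and numerical choices

The dichotomic search runs on the strictly increasing DPS column with the
lower-midpoint convention `(lo+hi)//2`; a target equal to a visited midpoint
terminates immediately with that row's stored ΔP. For an n-row table the
midpoint-comparison count is bounded by ⌈log₂ n⌉ (6 for the 48-row protocol
table). Between rows, two-point linear interpolation applies; at stored rows
the interpolant is exact, and it is continuous everywhere. Out-of-range
handling: below the first row the interpolant is anchored at the physical
zero (0 DPS → 0 ΔP), because zero flow must map to zero; above the last row
it extrapolates from the last two rows and flags the result, since that is
sensor-saturation territory. Volume integration is the trapezoidal rule with
V₀ = 0, exact for piecewise-linear flow.

Density modes: `off` (atmospheric pressure only, per-sample FiO₂),
`per_breath` (default — atmospheric pressure only, density frozen over each
ventilatory cycle and refreshed at the inspiratory onset; the cheap
embedded-style convention), and `per_sample` (absolute pressure = atmospheric
plus airway gauge pressure at every sample). The per-breath convention trades
a known 1.7–2.4%-class flow error (at airway pressures up to ~30 cmH₂O) for
far fewer arithmetic operations per 5 ms cycle; the error-budget module
quantifies exactly this trade.

## The virtual bench

The bench emulates the data the physical rig would produce.

*Waveform*: volume-control square inspiratory flow at VT/T_insp; passive
exponential expiration with time constant τ = R·C from a two-element lung
model (defaults R = 500 Pa/(L/s), C = 1.5·10⁻³ L/Pa, so τ = 0.75 s), peak
normalized so the expired volume within the expiratory window equals VT.
Because the trapezoidal rule loses half a sample at each flow discontinuity,
both branches are renormalized against their discrete per-period trapezoids;
per-breath true volumes then equal VT to numerical precision and the plateau
deviates from VT/T_insp by well under 1%. Airway pressure ramps from PEEP by
VT/C during inspiration and relaxes exponentially back. FiO₂ follows a
piecewise-constant schedule.

*Sensor*: DPS = sign(Q)·Q²ρ/(2·cd(|Q|)²·Ac²) + offset + Gaussian noise,
clipped at ±saturation. The true discharge-coefficient profile is
piecewise-linear with a 0.75 plateau over 7–8 L/min decaying to 0.65 below
4 and above 11 L/min — one concrete reading of the qualitative description
of the original device's Cd behaviour, configurable so alternative readings
plug in. Default noise is 0.05 Pa (the sensor class's offset-stability
scale); the physical density seen by the sensor always includes airway
pressure. The saturation default of 650 Pa places sensor clipping just above
the 80 L/min top of the calibration grid for the default geometry.

*Calibration emulation*: each grid set-point's DPS is the mean of 50 reads,
as a held set-point in a real rig spans many sampling intervals; this keeps
the low-flow rows strictly ordered under default noise.

What the bench does not emulate: patient effort (spontaneous breathing),
circuit leaks, actuator mechanics, humidity, and sensor drift over time. A
passing closed-loop test therefore demonstrates that the calibration/search/
integration pipeline inverts a variable-Cd sensor within margin under clean
volume-control conditions — not that a physical device meets the margin.

## Error-budget analyses

All sweeps are closed-form on the density/flow model (no lookup-table stage,
no finite differences): flow depends on density as ρ^(−1/2), so a wrong
assumed FiO₂ costs |√(M(true)/M(assumed)) − 1|, and omitting airway pressure
from P_abs costs |1 − √(p_atm/(p_atm + p_aw))|. The per-parameter sweep
re-evaluates the full model under one-at-a-time fractional perturbations:
Cd and Ac enter linearly, ΔP and the pressure/temperature family through the
square root. Within this model, total pressure and temperature enter at the
same (opposite-sign) power; the pressure family dominates the other density
parameters per unit fractional perturbation.

## Problem sizes and determinism

The test suite and the acceptance script run the closed-loop sweep at
3 breaths per tidal-volume setting (9 s at 5 ms sampling) across the 15
settings from 100 to 800 mL — enough cycles for the per-breath maximum to
stabilize, as the per-breath errors of a given setting agree to well under a
percent. All stochastic components (sensor noise) draw from one explicit
seed; identical seeds give bit-identical runs.

## Known limitations

- The mirrored-table treatment of expiration assumes the sensor transfer is
  symmetric in the flow direction; a physically asymmetric D-Lite would need
  a second calibration branch.
- The per-breath density mode freezes density at the inspiratory onset; a
  step change of FiO₂ mid-breath is picked up one cycle late.
- Linear interpolation between 5 L/min calibration steps above 40 L/min is
  the dominant table error at high flow; the protocol's 1 L/min spacing keeps
  the low-flow region tight.
- The breath segmenter is built for ventilator-driven cycles; very shallow
  breaths whose flow never clears the 2 L/min hysteresis merge into their
  neighbours.
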