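"""Synthetic virtual bench: ventilation waveforms and a virtual D-Lite sensor.

The bench stands in for the physical rig (flow source, lung model, gas
analyzer) so the calibration and estimation pipeline can be exercised
end-to-end in software. It emulates:

- a volume-control ventilation pattern: square inspiratory flow at
  VT / T_insp, passive exponential expiratory flow whose time constant
  comes from a two-element (resistance x compliance) lung model and whose
  peak is normalized so the expired volume within the expiratory window
  equals VT; airway pressure ramps from PEEP during inspiration by
  VT / compliance and relaxes back during expiration;
- a differential-pressure sensor whose *true* transfer follows the inverse
  Venturi relation with a flow-dependent discharge coefficient (a 0.75
  plateau at 7-8 L/min decaying to 0.65 away from it), plus configurable
  Gaussian noise, offset and saturation;
- the calibration protocol: a held flow set-point per grid value, the DPS
  reading averaged over repeated reads.

All randomness flows from one explicit seed; identical seeds give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, protocol_flow_grid
from .estimator import estimate_run, integrate_volume, segment_breaths
from .gas import AmbientConditions, DEFAULT_CONSTANTS, GasConstants, fio2_to_fractions, gas_density
from .venturi import DEFAULT_GEOMETRY, LPM_PER_M3S, PA_PER_CMH2O, VenturiGeometry

__all__ = [
    "CdProfile",
    "TrueSensorModel",
    "VentilationScenario",
    "generate_waveform",
    "virtual_sensor_read",
    "generate_calibration_run",
    "run_virtual_bench",
]


@dataclass(frozen=True)
class CdProfile:
    """Piecewise-linear true discharge coefficient vs |flow| (L/min).

    Default breakpoints give the plateau of 0.75 between 7 and 8 L/min
    decaying linearly to 0.65 below 4 and above 11 L/min, constant outside.
    """

    breakpoints_lpm: tuple[float, ...] = (4.0, 7.0, 8.0, 11.0)
    cd_values: tuple[float, ...] = (0.65, 0.75, 0.75, 0.65)

    def __post_init__(self) -> None:
        if len(self.breakpoints_lpm) != len(self.cd_values) or len(self.cd_values) < 1:
            raise ValueError("breakpoints and cd values must have equal nonzero length")
        if not all(0.0 < c <= 1.0 for c in self.cd_values):
            raise ValueError("discharge coefficients must be in (0, 1]")

    def __call__(self, flow_lpm):
        return np.interp(np.abs(flow_lpm), self.breakpoints_lpm, self.cd_values)

    @classmethod
    def constant(cls, cd: float) -> "CdProfile":
        return cls(breakpoints_lpm=(0.0,), cd_values=(cd,))


@dataclass(frozen=True)
class TrueSensorModel:
    """Ground-truth DPS transfer: variable-Cd Venturi + offset + noise + saturation."""

    cd_profile: CdProfile = field(default_factory=CdProfile)
    ac_m2: float = 58e-6
    noise_sd_pa: float = 0.05
    offset_pa: float = 0.0
    saturation_pa: float = 650.0

    def __post_init__(self) -> None:
        if self.noise_sd_pa < 0 or self.ac_m2 <= 0 or self.saturation_pa <= 0:
            raise ValueError("invalid sensor model parameters")


@dataclass(frozen=True)
class VentilationScenario:
    """Volume-control scenario: rate, I:E, tidal volume, PEEP, FiO2 schedule."""

    bpm: float = 20.0
    ie_ratio: float = 1.0  # inspiratory / expiratory time
    vt_ml: float = 600.0
    peep_cmh2o: float = 5.0
    fio2_schedule: tuple[tuple[float, float], ...] = ((0.0, 21.0),)  # (t_s, FiO2 %)
    amb: AmbientConditions = field(default_factory=lambda: AmbientConditions(81800.0, 293.15))
    duration_s: float = 9.0
    dt_s: float = 0.005
    compliance_l_per_pa: float = 1.5e-3
    resistance_pa_per_lps: float = 500.0

    def __post_init__(self) -> None:
        if self.bpm <= 0 or self.vt_ml < 0 or self.dt_s <= 0 or self.ie_ratio <= 0:
            raise ValueError("invalid scenario parameters")

    @property
    def period_s(self) -> float:
        return 60.0 / self.bpm

    @property
    def t_insp_s(self) -> float:
        return self.period_s * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp_s(self) -> float:
        return self.period_s - self.t_insp_s

    def fio2_at(self, t_s: np.ndarray) -> np.ndarray:
        sched = sorted(self.fio2_schedule)
        starts = np.asarray([s[0] for s in sched])
        vals = np.asarray([s[1] for s in sched])
        idx = np.clip(np.searchsorted(starts, t_s, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]


def generate_waveform(scenario: VentilationScenario, seed: int | None = None) -> pd.DataFrame:
    """Generate the true ventilation time series for a scenario.

    Returns a DataFrame with ``t_s, true_flow_lpm, p_airway_pa,
    fio2_percent``. Deterministic given the scenario (the seed argument is
    part of the reproducibility contract; the waveform itself is noise-free).
    """
    # include the endpoint so a duration that is a whole number of breath
    # periods closes its final breath window
    t = np.arange(0.0, scenario.duration_s + scenario.dt_s / 2, scenario.dt_s)
    phase = np.mod(t, scenario.period_s)
    insp = phase < scenario.t_insp_s

    vt_l = scenario.vt_ml / 1000.0
    q_insp_lpm = 0.0 if scenario.t_insp_s == 0 else vt_l / scenario.t_insp_s * 60.0

    tau = scenario.resistance_pa_per_lps * scenario.compliance_l_per_pa
    t_exp = scenario.t_exp_s
    # peak expiratory flow normalized so the expired volume over the
    # expiratory window equals VT despite the truncated exponential tail
    denom = tau * (1.0 - np.exp(-t_exp / tau)) if tau > 0 else t_exp
    q0_lps = 0.0 if denom == 0 else vt_l / denom
    te = phase - scenario.t_insp_s
    q_exp_lpm = -q0_lps * np.exp(-np.where(insp, 0.0, te) / tau) * 60.0

    flow = np.where(insp, q_insp_lpm, q_exp_lpm)
    if scenario.vt_ml == 0:
        flow = np.zeros_like(t)
    else:
        flow = _normalize_branch_volumes(t, flow, scenario)

    peep_pa = scenario.peep_cmh2o * PA_PER_CMH2O
    drive_pa = vt_l / scenario.compliance_l_per_pa if scenario.compliance_l_per_pa > 0 else 0.0
    frac_insp = np.where(insp, phase / max(scenario.t_insp_s, scenario.dt_s), 0.0)
    p_aw = peep_pa + drive_pa * np.where(
        insp, frac_insp, np.exp(-np.where(insp, 0.0, te) / max(tau, 1e-9))
    )
    if scenario.vt_ml == 0:
        p_aw = np.full_like(t, peep_pa)

    return pd.DataFrame(
        {
            "t_s": t,
            "true_flow_lpm": flow,
            "p_airway_pa": p_aw,
            "fio2_percent": scenario.fio2_at(t),
        }
    )


def _normalize_branch_volumes(t: np.ndarray, flow: np.ndarray, scenario: VentilationScenario) -> np.ndarray:
    """Rescale the inspiratory and expiratory branches so their discrete
    per-period trapezoids (positive / negative parts over one breath window,
    the segmentation convention) each equal VT.

    The continuous waveform moves VT per branch by construction, but the
    trapezoidal rule loses half a sample at each flow discontinuity; this
    folds that discretization loss back into the branch amplitudes.
    """
    i1 = int(round(scenario.period_s / scenario.dt_s))
    if i1 < 1 or i1 >= len(t):
        return flow
    from .estimator import integrate_volume as _integrate

    win_t = t[: i1 + 1]
    v_pos = _integrate(win_t, np.maximum(flow[: i1 + 1], 0.0))[-1]
    v_neg = -_integrate(win_t, np.minimum(flow[: i1 + 1], 0.0))[-1]
    s_pos = scenario.vt_ml / v_pos if v_pos > 0 else 1.0
    s_neg = scenario.vt_ml / v_neg if v_neg > 0 else 1.0
    return np.where(flow > 0, flow * s_pos, flow * s_neg)


def virtual_sensor_read(true_flow_lpm, model: TrueSensorModel, rho_kg_m3, rng: np.random.Generator | None = None):
    """True DPS reading(s) for given flow(s): inverse Venturi with the true Cd.

    dps = sign(Q) * Q^2 rho / (2 cd(|Q|)^2 Ac^2) + offset + noise, clipped
    at +/- saturation.
    """
    q = np.asarray(true_flow_lpm, dtype=float)
    rho = np.asarray(rho_kg_m3, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("gas density must be positive")
    cd = model.cd_profile(q)
    q_si = q / LPM_PER_M3S
    dps = np.sign(q_si) * q_si**2 * rho / (2.0 * cd**2 * model.ac_m2**2) + model.offset_pa
    if model.noise_sd_pa > 0:
        if rng is None:
            raise ValueError("a random generator is required when noise_sd_pa > 0")
        dps = dps + rng.normal(0.0, model.noise_sd_pa, size=np.shape(dps))
    dps = np.clip(dps, -model.saturation_pa, model.saturation_pa)
    return float(dps) if np.isscalar(true_flow_lpm) else dps


def generate_calibration_run(
    model: TrueSensorModel,
    amb: AmbientConditions,
    seed: int,
    flow_grid_lpm: Sequence[float] | None = None,
    constants: GasConstants = DEFAULT_CONSTANTS,
    n_avg: int = 50,
) -> list[tuple[float, float]]:
    """Emit (reference flow L/min, measured DPS Pa) calibration pairs.

    Air only, open circuit (no airway pressure). Each set-point's DPS is the
    mean of ``n_avg`` sensor reads, emulating a held flow sampled repeatedly.
    Default grid is the 48-point protocol.
    """
    rng = np.random.default_rng(seed)
    grid = protocol_flow_grid() if flow_grid_lpm is None else np.asarray(flow_grid_lpm, float)
    rho = gas_density(fio2_to_fractions(21.0), amb, constants, include_airway_pressure=False)
    pairs = []
    for q in grid:
        reads = virtual_sensor_read(np.full(n_avg, q), model, rho, rng)
        pairs.append((float(q), float(np.mean(reads))))
    return pairs


def sensor_run(
    scenario: VentilationScenario,
    model: TrueSensorModel,
    seed: int,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Waveform passed through the virtual sensor: the estimator's run format.

    The physical density seen by the sensor uses the full absolute pressure
    (atmospheric + airway) and the scheduled FiO2. Adds ``dps_pa`` and the
    ambient columns to the waveform frame.
    """
    rng = np.random.default_rng(seed)
    wf = generate_waveform(scenario, seed)
    rho_true = np.array(
        [
            gas_density(
                fio2_to_fractions(f),
                AmbientConditions(scenario.amb.p_atm_pa, scenario.amb.temperature_k, p),
                constants,
                include_airway_pressure=True,
            )
            for f, p in zip(wf["fio2_percent"], wf["p_airway_pa"])
        ]
    )
    wf["dps_pa"] = virtual_sensor_read(wf["true_flow_lpm"].to_numpy(), model, rho_true, rng)
    wf["p_atm_pa"] = scenario.amb.p_atm_pa
    wf["temp_k"] = scenario.amb.temperature_k
    return wf


def run_virtual_bench(
    scenario: VentilationScenario,
    model: TrueSensorModel,
    table: CalibrationTable,
    geom: VenturiGeometry = DEFAULT_GEOMETRY,
    constants: GasConstants = DEFAULT_CONSTANTS,
    *,
    density_mode: str = "per_breath",
    seed: int = 0,
) -> pd.DataFrame:
    """Closed loop: waveform -> virtual sensor -> estimator -> per-breath errors.

    Breath windows are segmented on the *true* flow so true and estimated
    volumes integrate over identical samples; each row compares the true and
    estimated inspired/expired volumes and reports relative errors.
    """
    run = sensor_run(scenario, model, seed, constants)
    est = estimate_run(run, table, geom, constants, density_mode=density_mode)

    t = run["t_s"].to_numpy()
    q_true = run["true_flow_lpm"].to_numpy()
    q_est = est["flow_lpm"].to_numpy()
    true_breaths = segment_breaths(t, q_true, fio2_percent=run["fio2_percent"].to_numpy())

    rows = []
    for br in true_breaths:
        i0 = int(np.searchsorted(t, br.t_start_s))
        i1 = int(np.searchsorted(t, br.t_end_s))
        if i1 <= i0:
            continue
        tw = t[i0 : i1 + 1]
        v_insp_est = integrate_volume(tw, np.maximum(q_est[i0 : i1 + 1], 0.0))[-1]
        v_exp_est = -integrate_volume(tw, np.minimum(q_est[i0 : i1 + 1], 0.0))[-1]
        rows.append(
            {
                "t_start_s": br.t_start_s,
                "t_end_s": br.t_end_s,
                "v_insp_true_ml": br.v_insp_ml,
                "v_insp_est_ml": v_insp_est,
                "v_exp_true_ml": br.v_exp_ml,
                "v_exp_est_ml": v_exp_est,
                "err_insp_rel": (v_insp_est - br.v_insp_ml) / br.v_insp_ml if br.v_insp_ml > 0 else 0.0,
                "err_exp_rel": (v_exp_est - br.v_exp_ml) / br.v_exp_ml if br.v_exp_ml > 0 else 0.0,
                "fio2_mean_percent": br.fio2_mean_percent,
            }
        )
    return pd.DataFrame(rows)
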