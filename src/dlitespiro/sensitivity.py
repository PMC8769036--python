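"""Error-budget analyses on the flow model, in closed form.

Flow depends on the model parameters as Q = Cd * Ac * sqrt(2 dP / rho)
with rho = P_abs * M_mix(FiO2) / (R T), so the relative flow error caused
by using a wrong parameter value is available exactly — no finite
differences, no data fit:

- wrong assumed FiO2:  err = |sqrt(rho(true)/rho(assumed)) - 1|
  (pressure and temperature cancel; only the mixture molar mass remains);
- omitting airway pressure from the absolute pressure:
  err = |1 - sqrt(p_atm / (p_atm + p_airway))|;
- a fractional perturbation of any single parameter: re-evaluate Q with
  the perturbed value and compare to the reference.

Each sweep returns a :class:`SensitivityCurve`; every curve passes
exactly through zero at the reference point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gas import AmbientConditions, DEFAULT_CONSTANTS, GasConstants, fio2_to_fractions, gas_density
from .venturi import VenturiGeometry, flow_from_dp

__all__ = [
    "SensitivityCurve",
    "fio2_assumption_error",
    "pressure_omission_error",
    "parameter_sensitivity",
    "plot_curves",
]


@dataclass(frozen=True)
class SensitivityCurve:
    """A swept parameter and the relative flow error (percent) at each grid point."""

    parameter: str
    grid: np.ndarray
    flow_error_percent: np.ndarray

    @property
    def max_abs_error_percent(self) -> float:
        return float(np.max(np.abs(self.flow_error_percent)))


def fio2_assumption_error(
    assumed_fio2_percent: float,
    true_fio2_grid: np.ndarray | None = None,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> SensitivityCurve:
    """Flow error from computing density with a fixed assumed FiO2.

    For each true FiO2 on the grid (default 21-100% in 1% steps) the error
    is |sqrt(M(true)/M(assumed)) - 1| * 100, the exact consequence of the
    rho^(-1/2) dependence of flow on density.
    """
    grid = np.arange(21.0, 101.0) if true_fio2_grid is None else np.asarray(true_fio2_grid, float)
    m_assumed = fio2_to_fractions(assumed_fio2_percent).molar_mass_kg_per_mol(constants)
    m_true = np.array([fio2_to_fractions(f).molar_mass_kg_per_mol(constants) for f in grid])
    err = np.abs(np.sqrt(m_true / m_assumed) - 1.0) * 100.0
    return SensitivityCurve(parameter=f"fio2_assumed_{assumed_fio2_percent:g}", grid=grid, flow_error_percent=err)


def pressure_omission_error(p_atm_pa: float, p_airway_grid_pa: np.ndarray) -> SensitivityCurve:
    """Flow error from omitting airway pressure in the density's absolute pressure.

    err = |1 - sqrt(p_atm / (p_atm + p_airway))| * 100 at each airway
    pressure on the grid.
    """
    if p_atm_pa <= 0:
        raise ValueError("atmospheric pressure must be positive")
    grid = np.asarray(p_airway_grid_pa, dtype=float)
    if np.any(p_atm_pa + grid <= 0):
        raise ValueError("absolute pressure must stay positive on the grid")
    err = np.abs(1.0 - np.sqrt(p_atm_pa / (p_atm_pa + grid))) * 100.0
    return SensitivityCurve(parameter="p_airway_omitted", grid=grid, flow_error_percent=err)


_SWEEP_PARAMS = ("p_atm", "p_airway", "temperature", "fio2", "cd", "ac", "dp")


def parameter_sensitivity(
    deltas: np.ndarray,
    *,
    p_atm_pa: float = 81800.0,
    p_airway_pa: float = 490.0,
    temperature_k: float = 293.15,
    fio2_percent: float = 21.0,
    cd: float = 0.7,
    ac_mm2: float = 58.0,
    dp_pa: float = 100.0,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> list[SensitivityCurve]:
    """One-at-a-time fractional perturbation of each model parameter.

    ``deltas`` are fractional perturbations (e.g. 0.01 for +1%). Each
    parameter in {p_atm, p_airway, temperature, fio2, cd, ac, dp} is
    perturbed alone and the flow re-evaluated exactly through the full
    density + Venturi model (absolute pressure includes airway pressure);
    the curve holds the signed relative flow error in percent.
    """
    deltas = np.asarray(deltas, dtype=float)
    ref = dict(
        p_atm=p_atm_pa, p_airway=p_airway_pa, temperature=temperature_k,
        fio2=fio2_percent, cd=cd, ac=ac_mm2, dp=dp_pa,
    )

    def flow(p: dict) -> float:
        comp = fio2_to_fractions(min(max(p["fio2"], 21.0), 100.0))
        amb = AmbientConditions(p["p_atm"], p["temperature"], p["p_airway"])
        rho = gas_density(comp, amb, constants, include_airway_pressure=True)
        return flow_from_dp(p["dp"], rho, VenturiGeometry(cd=p["cd"], ac_mm2=p["ac"]))

    q_ref = flow(ref)
    curves = []
    for name in _SWEEP_PARAMS:
        errs = np.empty_like(deltas)
        for k, d in enumerate(deltas):
            pert = dict(ref)
            pert[name] = ref[name] * (1.0 + d)
            errs[k] = (flow(pert) - q_ref) / q_ref * 100.0
        curves.append(SensitivityCurve(parameter=name, grid=deltas, flow_error_percent=errs))
    return curves


def plot_curves(curves: list[SensitivityCurve], path: str, *, xlabel: str = "swept value", title: str = "") -> None:
    """Write a figure with one line per sensitivity curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        ax.plot(c.grid, c.flow_error_percent, label=c.parameter)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("flow error [%]")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    ax.grid(True, alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
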