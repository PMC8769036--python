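"""Gas-mixture composition and ideal-gas density.

The ventilation circuit carries a two-component volumetric blend of air
(21% O2) and supplemental pure oxygen. The fraction of inspired oxygen
(FiO2, percent) determines the blend, the blend determines the mixture
molar mass, and the ideal-gas law gives the density that enters the
Venturi flow model:

    rho = P_abs * M_mix / (R * T)

with M_mix the volume-weighted molar mass and P_abs the absolute pressure
(atmospheric, optionally plus airway gauge pressure). Everything internal
is SI: Pa, K, kg/m3.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "GasConstants",
    "GasComposition",
    "AmbientConditions",
    "DEFAULT_CONSTANTS",
    "O2_IN_AIR_PERCENT",
    "fio2_to_fractions",
    "fio2_from_fractions",
    "gas_density",
]

#: Oxygen volume percent of dry air; defines the FiO2 = 21% endpoint.
O2_IN_AIR_PERCENT = 21.0

_FIO2_TOL = 1e-9


@dataclass(frozen=True)
class GasConstants:
    """Molar masses (g/mol) and the universal gas constant (J/(mol K)).

    Defaults are the standard handbook values; all are overridable so that
    instrument-specific constants can be dropped in.
    """

    m_air_g_per_mol: float = 28.97
    m_o2_g_per_mol: float = 31.999
    r_j_per_mol_k: float = 8.314

    def __post_init__(self) -> None:
        if not (self.m_air_g_per_mol > 0 and self.m_o2_g_per_mol > 0 and self.r_j_per_mol_k > 0):
            raise ValueError("gas constants must be strictly positive")
        if not self.m_o2_g_per_mol > self.m_air_g_per_mol:
            raise ValueError("molar mass of O2 must exceed that of air")


DEFAULT_CONSTANTS = GasConstants()


@dataclass(frozen=True)
class GasComposition:
    """Volumetric air/O2 blend corresponding to an FiO2 setting."""

    fio2_percent: float
    v_air_percent: float
    v_o2_percent: float

    def __post_init__(self) -> None:
        if abs(self.v_air_percent + self.v_o2_percent - 100.0) > 1e-9:
            raise ValueError("air and O2 volume percentages must sum to 100")
        if not (0.0 <= self.v_air_percent <= 100.0 and 0.0 <= self.v_o2_percent <= 100.0):
            raise ValueError("volume percentages must lie in [0, 100]")

    def molar_mass_kg_per_mol(self, constants: GasConstants = DEFAULT_CONSTANTS) -> float:
        """Volume-weighted mixture molar mass, in kg/mol."""
        m_g = (
            self.v_air_percent * constants.m_air_g_per_mol
            + self.v_o2_percent * constants.m_o2_g_per_mol
        ) / 100.0
        return m_g * 1e-3


@dataclass(frozen=True)
class AmbientConditions:
    """Ambient state: atmospheric pressure, temperature, airway gauge pressure (Pa, K, Pa)."""

    p_atm_pa: float
    temperature_k: float
    p_airway_pa: float = 0.0

    def __post_init__(self) -> None:
        if self.p_atm_pa <= 0:
            raise ValueError("atmospheric pressure must be positive")
        if self.temperature_k <= 0:
            raise ValueError("absolute temperature must be positive")
        if self.p_airway_pa < -self.p_atm_pa:
            raise ValueError("airway gauge pressure may not drive absolute pressure negative")


def fio2_to_fractions(fio2_percent: float, *, o2_in_air_percent: float = O2_IN_AIR_PERCENT) -> GasComposition:
    """Split an FiO2 setting into air / supplemental-O2 volume fractions.

    Solves the linear mixing model

        fio2 = (o2_in_air * v_air + 100 * v_o2) / 100,   v_air + v_o2 = 100

    so FiO2 = 21% maps to pure air and FiO2 = 100% to pure O2. Values
    slightly below 21% (down to 0) are clamped to 21% with a warning —
    FiO2 cells drift; a reading below the air endpoint is physically air.

    Raises
    ------
    ValueError
        If ``fio2_percent`` is below 0 or above 100 beyond tolerance.
    """
    if fio2_percent < -_FIO2_TOL or fio2_percent > 100.0 + _FIO2_TOL:
        raise ValueError(f"FiO2 of {fio2_percent}% is outside the physical range [0, 100]")
    fio2 = min(float(fio2_percent), 100.0)
    if fio2 < o2_in_air_percent:
        warnings.warn(
            f"FiO2 of {fio2}% is below the air endpoint ({o2_in_air_percent}%); clamping",
            stacklevel=2,
        )
        fio2 = o2_in_air_percent
    v_o2 = (fio2 - o2_in_air_percent) / (100.0 - o2_in_air_percent) * 100.0
    return GasComposition(fio2_percent=fio2, v_air_percent=100.0 - v_o2, v_o2_percent=v_o2)


def fio2_from_fractions(comp: GasComposition, *, o2_in_air_percent: float = O2_IN_AIR_PERCENT) -> float:
    """Recompose FiO2 from the blend fractions (exact inverse of the mixing model)."""
    return (o2_in_air_percent * comp.v_air_percent + 100.0 * comp.v_o2_percent) / 100.0


def gas_density(
    comp: GasComposition,
    amb: AmbientConditions,
    constants: GasConstants = DEFAULT_CONSTANTS,
    *,
    include_airway_pressure: bool = False,
) -> float:
    """Ideal-gas density of the mixture, kg/m3.

    ``include_airway_pressure`` selects the absolute pressure: atmospheric
    only (the cheap per-breath convention) or atmospheric plus airway gauge
    pressure (the per-sample convention).
    """
    p_abs = amb.p_atm_pa + (amb.p_airway_pa if include_airway_pressure else 0.0)
    if p_abs <= 0:
        raise ValueError("absolute pressure must be positive")
    return p_abs * comp.molar_mass_kg_per_mol(constants) / (constants.r_j_per_mol_k * amb.temperature_k)
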