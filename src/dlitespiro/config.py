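"""Run configuration: every method constant as a named, overridable default.

The flat YAML schema mirrors the config keys:

    gas.m_air_g_per_mol: 28.97
    gas.m_o2_g_per_mol: 31.999
    gas.r_j_per_mol_k: 8.314
    venturi.cd: 0.7
    venturi.ac_mm2: 58.0
    density.airway_pressure_mode: per_breath   # off | per_breath | per_sample
    sampling.dt_s: 0.005
    breaths.hysteresis_lpm: 2.0
    breaths.min_duration_s: 0.05
    seed: 0
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .estimator import DEFAULT_DT_S, DEFAULT_HYSTERESIS_LPM, DEFAULT_HYSTERESIS_S
from .gas import GasConstants
from .venturi import VenturiGeometry

__all__ = ["RunConfig", "load_config"]

_DENSITY_MODES = ("off", "per_breath", "per_sample")


@dataclass(frozen=True)
class RunConfig:
    constants: GasConstants = field(default_factory=GasConstants)
    geometry: VenturiGeometry = field(default_factory=VenturiGeometry)
    density_mode: str = "per_breath"
    dt_s: float = DEFAULT_DT_S
    hysteresis_lpm: float = DEFAULT_HYSTERESIS_LPM
    min_duration_s: float = DEFAULT_HYSTERESIS_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_mode not in _DENSITY_MODES:
            raise ValueError(f"density mode must be one of {_DENSITY_MODES}")
        if self.dt_s <= 0 or self.hysteresis_lpm < 0 or self.min_duration_s < 0:
            raise ValueError("invalid sampling or breath-segmentation settings")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; a missing path returns all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    gas = raw.get("gas", {})
    ven = raw.get("venturi", {})
    dens = raw.get("density", {})
    samp = raw.get("sampling", {})
    br = raw.get("breaths", {})
    return RunConfig(
        constants=GasConstants(
            m_air_g_per_mol=gas.get("m_air_g_per_mol", GasConstants.m_air_g_per_mol),
            m_o2_g_per_mol=gas.get("m_o2_g_per_mol", GasConstants.m_o2_g_per_mol),
            r_j_per_mol_k=gas.get("r_j_per_mol_k", GasConstants.r_j_per_mol_k),
        ),
        geometry=VenturiGeometry(
            cd=ven.get("cd", VenturiGeometry.cd),
            ac_mm2=ven.get("ac_mm2", VenturiGeometry.ac_mm2),
        ),
        density_mode=dens.get("airway_pressure_mode", "per_breath"),
        dt_s=samp.get("dt_s", DEFAULT_DT_S),
        hysteresis_lpm=br.get("hysteresis_lpm", DEFAULT_HYSTERESIS_LPM),
        min_duration_s=br.get("min_duration_s", DEFAULT_HYSTERESIS_S),
        seed=int(raw.get("seed", 0)),
    )
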