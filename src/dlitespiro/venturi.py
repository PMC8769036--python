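"""Forward and inverse Venturi flow model.

Flow through the D-Lite constriction follows

    Q = Cd * Ac * sqrt(2 * dP / rho)

with Cd the discharge coefficient, Ac the total port cross-section and
dP the differential pressure between the two flow ports. The inverse,

    dP = Q^2 * rho / (2 * Cd^2 * Ac^2),

is what the calibration stage stores. Computation is SI throughout
(Pa, m2, kg/m3, m3/s); flows cross the API boundary in L/min and the
port area is configured in mm2. Both directions (inspiration and
expiration) are handled by odd extension: the sign of the result follows
the sign of the input.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VenturiGeometry", "DEFAULT_GEOMETRY", "flow_from_dp", "dp_from_flow", "LPM_PER_M3S", "PA_PER_CMH2O"]

#: 1 m3/s in L/min.
LPM_PER_M3S = 60000.0
#: 1 cm H2O in Pa (display-boundary conversion only).
PA_PER_CMH2O = 98.0665


@dataclass(frozen=True)
class VenturiGeometry:
    """Discharge coefficient and total port cross-section (configured in mm2)."""

    cd: float = 0.7
    ac_mm2: float = 58.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cd <= 1.0:
            raise ValueError("discharge coefficient must be in (0, 1]")
        if self.ac_mm2 <= 0:
            raise ValueError("port cross-section must be positive")

    @property
    def ac_m2(self) -> float:
        return self.ac_mm2 * 1e-6


DEFAULT_GEOMETRY = VenturiGeometry()


def flow_from_dp(dp_pa, rho_kg_m3, geom: VenturiGeometry = DEFAULT_GEOMETRY):
    """Flow (L/min, signed) from differential pressure (Pa, signed).

    Accepts scalars or numpy arrays; the sign of the flow follows the sign
    of the differential pressure.
    """
    rho = np.asarray(rho_kg_m3, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("gas density must be positive")
    dp = np.asarray(dp_pa, dtype=float)
    q_si = geom.cd * geom.ac_m2 * np.sqrt(2.0 * np.abs(dp) / rho)
    q = np.sign(dp) * q_si * LPM_PER_M3S
    return float(q) if np.isscalar(dp_pa) else q


def dp_from_flow(q_lpm, rho_kg_m3, geom: VenturiGeometry = DEFAULT_GEOMETRY):
    """Differential pressure (Pa, signed) from flow (L/min, signed).

    Exact algebraic inverse of :func:`flow_from_dp`.
    """
    rho = np.asarray(rho_kg_m3, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("gas density must be positive")
    q_si = np.asarray(q_lpm, dtype=float) / LPM_PER_M3S
    dp = np.sign(q_si) * (q_si**2) * rho / (2.0 * geom.cd**2 * geom.ac_m2**2)
    return float(dp) if np.isscalar(q_lpm) else dp
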