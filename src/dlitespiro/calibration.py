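"""Build, validate and persist the two-column calibration lookup table.

Calibration pairs a regulated reference flow (from a gas analyzer) with
the raw differential-pressure-sensor (DPS) reading at that flow. For each
pair the model differential pressure is computed from the inverse Venturi
relation at the fixed design constants (Cd = 0.7, Ac = 58 mm2) and air
density. The stored table — column 1 the measured DPS, column 2 the model
dP, sorted by column 1 — is what the runtime estimator searches: the
per-row ratio dP_model / DPS absorbs the flow-dependent discharge
coefficient and any geometry deviation without fitting a regression.

The protocol grid samples every 1 L/min from 1 to 40 (where low-flow,
trigger-relevant accuracy matters most) then every 5 L/min up to the
sensor saturation point around 80 L/min, giving 48 rows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gas import AmbientConditions, DEFAULT_CONSTANTS, GasConstants, fio2_to_fractions, gas_density
from .venturi import DEFAULT_GEOMETRY, VenturiGeometry, dp_from_flow

__all__ = [
    "CalibrationRecord",
    "CalibrationTable",
    "ValidationReport",
    "protocol_flow_grid",
    "build_table",
    "validate_table",
    "write_table",
    "read_table",
]

#: DPS readings closer than this are treated as duplicates and merged.
#: Matches the sensor's stated offset-stability scale (0.01 Pa).
DPS_MERGE_TOL_PA = 0.01


@dataclass(frozen=True)
class CalibrationRecord:
    """One table row: measured DPS (Pa), model dP (Pa), reference flow (L/min)."""

    dps_measured_pa: float
    dp_model_pa: float
    flow_ref_lpm: float


@dataclass(frozen=True)
class CalibrationTable:
    """Sorted lookup array mapping measured DPS readings to model dP values.

    Column 1 (``dps``) must be strictly increasing; column 2 (``dp_model``)
    should be non-decreasing for a healthy sensor (a violation is a fault
    indicator and raises a warning, not an error).
    """

    dps: np.ndarray
    dp_model: np.ndarray
    flow_ref: np.ndarray
    created_density_kg_m3: float
    geometry: VenturiGeometry = field(default=DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dps", np.asarray(self.dps, dtype=float))
        object.__setattr__(self, "dp_model", np.asarray(self.dp_model, dtype=float))
        object.__setattr__(self, "flow_ref", np.asarray(self.flow_ref, dtype=float))
        if self.dps.ndim != 1 or self.dps.shape != self.dp_model.shape or self.dps.shape != self.flow_ref.shape:
            raise ValueError("table columns must be 1-D and of equal length")
        if self.n < 2:
            raise ValueError("calibration table needs at least 2 rows")
        if not np.all(np.diff(self.dps) > 0):
            raise ValueError("measured DPS column must be strictly increasing")
        if np.any(np.diff(self.dp_model) < 0):
            warnings.warn(
                "model dP column is not non-decreasing; possible sensor fault in the calibration data",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return int(self.dps.shape[0])

    @property
    def records(self) -> list[CalibrationRecord]:
        return [
            CalibrationRecord(float(d), float(m), float(f))
            for d, m, f in zip(self.dps, self.dp_model, self.flow_ref)
        ]


@dataclass(frozen=True)
class ValidationReport:
    n_rows: int
    dps_min_pa: float
    dps_max_pa: float
    monotonicity_violations: int
    adjustment_factors: np.ndarray  # per-row dp_model / dps_measured

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_rows} rows, DPS coverage [{self.dps_min_pa:.3g}, {self.dps_max_pa:.3g}] Pa, "
            f"{self.monotonicity_violations} monotonicity violation(s), "
            f"adjustment factors in [{self.adjustment_factors.min():.4f}, {self.adjustment_factors.max():.4f}]"
        )


def protocol_flow_grid(
    *, fine_stop_lpm: float = 40.0, coarse_step_lpm: float = 5.0, saturation_lpm: float = 80.0
) -> np.ndarray:
    """The calibration protocol's flow grid, L/min.

    1 L/min steps from 1 up to ``fine_stop_lpm``, then ``coarse_step_lpm``
    steps up to the sensor saturation flow. Defaults give 48 points.
    """
    fine = np.arange(1.0, fine_stop_lpm + 0.5)
    coarse = np.arange(fine_stop_lpm + coarse_step_lpm, saturation_lpm + coarse_step_lpm / 2, coarse_step_lpm)
    return np.concatenate([fine, coarse])


def build_table(
    pairs: Iterable[tuple[float, float]],
    amb: AmbientConditions,
    geom: VenturiGeometry = DEFAULT_GEOMETRY,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> CalibrationTable:
    """Build a calibration table from (reference flow L/min, measured DPS Pa) pairs.

    Calibration runs on air in an open circuit, so the density uses FiO2 = 21%
    and atmospheric pressure only. Pairs are sorted by DPS; readings within
    ``DPS_MERGE_TOL_PA`` of each other are merged by averaging (binary search
    needs strict ordering).
    """
    pairs = [(float(q), float(d)) for q, d in pairs]
    if len(pairs) < 2:
        raise ValueError("calibration needs at least 2 (flow, DPS) pairs")
    if any(q < 0 for q, _ in pairs):
        raise ValueError("calibration flows must be non-negative (protocol uses positive flow only)")

    rho = gas_density(fio2_to_fractions(21.0), amb, constants, include_airway_pressure=False)
    rows = sorted(((d, dp_from_flow(q, rho, geom), q) for q, d in pairs), key=lambda r: r[0])

    merged: list[list[float]] = []
    for dps, dp_model, q in rows:
        if merged and dps - merged[-1][0] <= DPS_MERGE_TOL_PA:
            grp = merged[-1]
            k = grp[3]
            grp[0] = (grp[0] * k + dps) / (k + 1)
            grp[1] = (grp[1] * k + dp_model) / (k + 1)
            grp[2] = (grp[2] * k + q) / (k + 1)
            grp[3] = k + 1
        else:
            merged.append([dps, dp_model, q, 1.0])
    if len(merged) < 2:
        raise ValueError("fewer than 2 distinct DPS readings after merging duplicates")

    arr = np.asarray([m[:3] for m in merged], dtype=float)
    return CalibrationTable(
        dps=arr[:, 0], dp_model=arr[:, 1], flow_ref=arr[:, 2],
        created_density_kg_m3=rho, geometry=geom,
    )


def validate_table(table: CalibrationTable) -> ValidationReport:
    """Report-only structural check: monotonicity, coverage, adjustment factors."""
    violations = int(np.sum(np.diff(table.dp_model) < 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(table.dps != 0, table.dp_model / table.dps, np.nan)
    return ValidationReport(
        n_rows=table.n,
        dps_min_pa=float(table.dps[0]),
        dps_max_pa=float(table.dps[-1]),
        monotonicity_violations=violations,
        adjustment_factors=factors,
    )


def write_table(table: CalibrationTable, path: str | Path) -> None:
    """Persist a table as commented CSV: ``dps_pa,dp_model_pa,flow_ref_lpm``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# dlitespiro calibration table, n={table.n}\n")
        fh.write(f"# created_density_kg_m3={table.created_density_kg_m3!r}\n")
        fh.write(f"# cd={table.geometry.cd!r}\n")
        fh.write(f"# ac_mm2={table.geometry.ac_mm2!r}\n")
        fh.write("dps_pa,dp_model_pa,flow_ref_lpm\n")
        for d, m, f in zip(table.dps, table.dp_model, table.flow_ref):
            fh.write(f"{float(d)!r},{float(m)!r},{float(f)!r}\n")


def read_table(path: str | Path) -> CalibrationTable:
    """Read a persisted table, re-checking all structural invariants.

    Raises
    ------
    ValueError
        On a malformed file or a non-monotone DPS column.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    try:
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed calibration table file {path}: {exc}") from exc
    required = {"dps_pa", "dp_model_pa", "flow_ref_lpm"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration table {path} is missing columns {sorted(required - set(df.columns))}")
    geom = VenturiGeometry(cd=meta.get("cd", DEFAULT_GEOMETRY.cd), ac_mm2=meta.get("ac_mm2", DEFAULT_GEOMETRY.ac_mm2))
    return CalibrationTable(
        dps=df["dps_pa"].to_numpy(float),
        dp_model=df["dp_model_pa"].to_numpy(float),
        flow_ref=df["flow_ref_lpm"].to_numpy(float),
        created_density_kg_m3=meta.get("created_density_kg_m3", float("nan")),
        geometry=geom,
    )
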