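"""Runtime flow and volume estimation.

The runtime path per sample is: locate the measured DPS reading in the
stored calibration table by dichotomic (binary) search, linearly
interpolate the model dP between the bracketing rows,

    dP = dP0 + (DPS - DPS0) / (DPS1 - DPS0) * (dP1 - dP0),

convert dP to flow through the Venturi relation with the FiO2-corrected
gas density, and accumulate tidal volume by the trapezoidal rule

    V_k = V_{k-1} + dt * (Q_k + Q_{k-1}) / 2.

The table stores the positive (inspiratory) branch only; expiration is
handled by searching |DPS| and re-applying the sign. Below the first row
the interpolant is anchored at the physical zero (0 DPS -> 0 dP); above
the last row it extrapolates from the last two rows and flags the result
(sensor saturation territory).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationTable
from .gas import (
    AmbientConditions,
    DEFAULT_CONSTANTS,
    GasConstants,
    fio2_to_fractions,
    gas_density,
)
from .venturi import DEFAULT_GEOMETRY, VenturiGeometry, flow_from_dp

__all__ = [
    "VentilationSample",
    "LookupResult",
    "BreathResult",
    "lookup_dp",
    "estimate_flow",
    "estimate_run",
    "integrate_volume",
    "segment_breaths",
    "DEFAULT_DT_S",
    "DEFAULT_HYSTERESIS_LPM",
    "DEFAULT_HYSTERESIS_S",
]

#: Nominal sampling interval of the flow/volume loop, s.
DEFAULT_DT_S = 0.005
#: Breath-segmentation hysteresis: flow magnitude and persistence required
#: to accept an inspiratory onset (trigger flows span roughly 1-20 L/min).
DEFAULT_HYSTERESIS_LPM = 2.0
DEFAULT_HYSTERESIS_S = 0.05


@dataclass(frozen=True)
class VentilationSample:
    """One timestamped sensor frame."""

    t_s: float
    dps_pa: float
    p_airway_pa: float
    fio2_percent: float
    amb: AmbientConditions


@dataclass(frozen=True)
class LookupResult:
    """Outcome of one table lookup: interpolated dP plus search diagnostics."""

    dp_pa: float
    idx_lo: int
    idx_hi: int
    steps: int
    extrapolated: bool


@dataclass(frozen=True)
class BreathResult:
    """Per-breath summary: inspired/expired volume, peak flow, mean FiO2."""

    t_start_s: float
    t_end_s: float
    v_insp_ml: float
    v_exp_ml: float
    q_peak_lpm: float
    fio2_mean_percent: float


def lookup_dp(table: CalibrationTable, dps_pa: float) -> LookupResult:
    """Dichotomic search + linear interpolation of the model dP for a DPS reading.

    The search operates on |DPS| and the sign is re-applied to the result.
    ``steps`` counts midpoint comparisons; for an n-row table it is bounded
    by ceil(log2 n). A target equal to a stored reading (including a visited
    midpoint) returns that row's dP exactly.
    """
    x = abs(float(dps_pa))
    sign = 1.0 if dps_pa >= 0 else -1.0
    dps, dpm = table.dps, table.dp_model
    n = table.n

    if x <= dps[0]:
        if x == dps[0]:
            return LookupResult(sign * float(dpm[0]), 0, 0, 0, False)
        # below the stored range: anchor the interpolant at the physical zero
        dp = x / dps[0] * dpm[0] if dps[0] > 0 else 0.0
        return LookupResult(sign * float(dp), -1, 0, 0, False)
    if x >= dps[n - 1]:
        if x == dps[n - 1]:
            return LookupResult(sign * float(dpm[n - 1]), n - 1, n - 1, 0, False)
        slope = (dpm[n - 1] - dpm[n - 2]) / (dps[n - 1] - dps[n - 2])
        dp = dpm[n - 1] + (x - dps[n - 1]) * slope
        return LookupResult(sign * float(dp), n - 2, n - 1, 0, True)

    lo, hi, steps = 0, n - 1, 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        steps += 1
        if x == dps[mid]:
            return LookupResult(sign * float(dpm[mid]), mid, mid, steps, False)
        if x < dps[mid]:
            hi = mid
        else:
            lo = mid
    frac = (x - dps[lo]) / (dps[hi] - dps[lo])
    dp = dpm[lo] + frac * (dpm[hi] - dpm[lo])
    return LookupResult(sign * float(dp), lo, hi, steps, False)


def max_search_steps(n: int) -> int:
    """Worst-case midpoint comparisons for an n-row table: ceil(log2(n-1))."""
    return max(0, math.ceil(math.log2(n - 1))) if n > 1 else 0


def estimate_flow(
    sample: VentilationSample,
    table: CalibrationTable,
    geom: VenturiGeometry = DEFAULT_GEOMETRY,
    constants: GasConstants = DEFAULT_CONSTANTS,
    *,
    include_airway_pressure: bool = False,
) -> float:
    """Estimate the flow (L/min, signed) for a single sensor frame."""
    res = lookup_dp(table, sample.dps_pa)
    amb = AmbientConditions(sample.amb.p_atm_pa, sample.amb.temperature_k, sample.p_airway_pa)
    rho = gas_density(
        fio2_to_fractions(sample.fio2_percent), amb, constants,
        include_airway_pressure=include_airway_pressure,
    )
    return flow_from_dp(res.dp_pa, rho, geom)


def estimate_run(
    run: pd.DataFrame,
    table: CalibrationTable,
    geom: VenturiGeometry = DEFAULT_GEOMETRY,
    constants: GasConstants = DEFAULT_CONSTANTS,
    *,
    density_mode: str = "per_breath",
) -> pd.DataFrame:
    """Estimate flow for a whole ventilation run.

    ``run`` needs columns ``t_s, dps_pa, p_airway_pa, fio2_percent,
    p_atm_pa, temp_k``. Density modes:

    - ``off``: atmospheric pressure only, density follows FiO2 per sample;
    - ``per_breath`` (default): atmospheric pressure only, density frozen at
      the start of each ventilatory cycle (DPS sign change to positive) —
      one density value per cycle, the cheap embedded-style convention;
    - ``per_sample``: absolute pressure = atmospheric + airway each sample.

    Returns a copy of ``run`` with added columns ``dp_pa``, ``rho_kg_m3``,
    ``flow_lpm``, ``extrapolated``.
    """
    if density_mode not in ("off", "per_breath", "per_sample"):
        raise ValueError(f"unknown density mode {density_mode!r}")
    t = run["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("run timestamps must be strictly increasing")
    dps = run["dps_pa"].to_numpy(float)
    p_aw = run["p_airway_pa"].to_numpy(float)
    fio2 = run["fio2_percent"].to_numpy(float)
    p_atm = run["p_atm_pa"].to_numpy(float)
    temp = run["temp_k"].to_numpy(float)

    n = len(t)
    dp = np.empty(n)
    extrap = np.zeros(n, dtype=bool)
    for i in range(n):
        res = lookup_dp(table, dps[i])
        dp[i] = res.dp_pa
        extrap[i] = res.extrapolated

    rho = np.empty(n)
    if density_mode == "per_breath":
        # freeze density over each cycle; recompute at inspiratory onsets
        rho_now = gas_density(
            fio2_to_fractions(fio2[0]), AmbientConditions(p_atm[0], temp[0]), constants,
            include_airway_pressure=False,
        )
        for i in range(n):
            if i > 0 and dps[i] > 0 >= dps[i - 1]:
                rho_now = gas_density(
                    fio2_to_fractions(fio2[i]), AmbientConditions(p_atm[i], temp[i]), constants,
                    include_airway_pressure=False,
                )
            rho[i] = rho_now
    else:
        include = density_mode == "per_sample"
        for i in range(n):
            rho[i] = gas_density(
                fio2_to_fractions(fio2[i]),
                AmbientConditions(p_atm[i], temp[i], p_aw[i]),
                constants,
                include_airway_pressure=include,
            )

    out = run.copy()
    out["dp_pa"] = dp
    out["rho_kg_m3"] = rho
    out["flow_lpm"] = flow_from_dp(dp, rho, geom)
    out["extrapolated"] = extrap
    return out


def integrate_volume(t_s: np.ndarray, q_lpm: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal volume (mL) of a flow series, V[0] = 0.

    Accepts irregular timestamps; 1 L/min = 1000/60 mL/s.
    """
    t = np.asarray(t_s, dtype=float)
    q = np.asarray(q_lpm, dtype=float) * (1000.0 / 60.0)  # mL/s
    if t.ndim != 1 or t.shape != q.shape:
        raise ValueError("time and flow must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    v = np.zeros_like(t)
    if len(t) > 1:
        v[1:] = np.cumsum(np.diff(t) * (q[1:] + q[:-1]) / 2.0)
    return v


def segment_breaths(
    t_s: np.ndarray,
    q_lpm: np.ndarray,
    *,
    fio2_percent: np.ndarray | None = None,
    hysteresis_lpm: float = DEFAULT_HYSTERESIS_LPM,
    min_duration_s: float = DEFAULT_HYSTERESIS_S,
) -> list[BreathResult]:
    """Split a signed flow series into breaths and integrate per-breath volumes.

    A breath starts where flow rises above ``+hysteresis_lpm`` and stays
    there for at least ``min_duration_s`` (inspiratory onset). Within each
    breath, the inspired volume integrates the positive part of the flow
    and the expired volume the negative part. A series with no qualifying
    onset is returned as one open breath.
    """
    t = np.asarray(t_s, dtype=float)
    q = np.asarray(q_lpm, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    fio2 = None if fio2_percent is None else np.asarray(fio2_percent, dtype=float)

    onsets = _inspiratory_onsets(t, q, hysteresis_lpm, min_duration_s)
    if not onsets:
        bounds = [(0, len(t) - 1)]
    else:
        bounds = [
            (onsets[k], onsets[k + 1] if k + 1 < len(onsets) else len(t) - 1)
            for k in range(len(onsets))
        ]

    breaths = []
    for i0, i1 in bounds:
        if i1 <= i0:
            continue
        tw, qw = t[i0 : i1 + 1], q[i0 : i1 + 1]
        v_pos = integrate_volume(tw, np.maximum(qw, 0.0))[-1]
        v_neg = -integrate_volume(tw, np.minimum(qw, 0.0))[-1]
        breaths.append(
            BreathResult(
                t_start_s=float(tw[0]),
                t_end_s=float(tw[-1]),
                v_insp_ml=float(v_pos),
                v_exp_ml=float(v_neg),
                q_peak_lpm=float(np.max(np.abs(qw))),
                fio2_mean_percent=float(np.mean(fio2[i0 : i1 + 1])) if fio2 is not None else float("nan"),
            )
        )
    return breaths


def _inspiratory_onsets(t, q, hysteresis_lpm, min_duration_s) -> list[int]:
    onsets: list[int] = []
    in_insp = False
    i, n = 0, len(t)
    while i < n:
        if not in_insp and q[i] >= hysteresis_lpm:
            # require the flow to persist above threshold for min_duration_s
            j = i
            while j < n and q[j] >= hysteresis_lpm:
                j += 1
            if (j - 1 > i and t[j - 1] - t[i] >= min_duration_s) or (j == n and n - i > 1):
                onsets.append(i)
                in_insp = True
            i = j
        elif in_insp and q[i] <= -hysteresis_lpm:
            in_insp = False
            i += 1
        else:
            i += 1
    return onsets
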