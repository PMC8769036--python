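"""Shared delimited-text readers/writers for the pipeline file formats.

All files are comma-separated UTF-8 with a mandatory header row; ``#``
comment lines are permitted before the header. Formats:

- calibration pairs:   ``flow_ref_lpm,dps_pa``
- ventilation run:     ``t_s,dps_pa,p_airway_pa,fio2_percent,p_atm_pa,temp_k``
  (simulated runs add ``true_flow_lpm``)
- flow series:         ``t_s,flow_lpm`` (+ optional passthrough columns)
- breath summary:      ``t_start_s,t_end_s,v_insp_ml,v_exp_ml,q_peak_lpm,fio2_mean_percent``
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .estimator import BreathResult

RUN_COLUMNS = ["t_s", "dps_pa", "p_airway_pa", "fio2_percent", "p_atm_pa", "temp_k"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed or unreadable CSV file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns {missing}")
    return df


def read_pairs(path: str | Path) -> list[tuple[float, float]]:
    df = _read_csv(path, ["flow_ref_lpm", "dps_pa"])
    return list(zip(df["flow_ref_lpm"].astype(float), df["dps_pa"].astype(float)))


def write_pairs(pairs: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["flow_ref_lpm", "dps_pa"]).to_csv(path, index=False)


def read_run(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, RUN_COLUMNS)


def write_run(run: pd.DataFrame, path: str | Path) -> None:
    run.to_csv(path, index=False)


def read_flows(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["t_s", "flow_lpm"])


def write_flows(flows: pd.DataFrame, path: str | Path) -> None:
    flows.to_csv(path, index=False)


def write_breaths(breaths: list[BreathResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "t_start_s": b.t_start_s,
                "t_end_s": b.t_end_s,
                "v_insp_ml": b.v_insp_ml,
                "v_exp_ml": b.v_exp_ml,
                "q_peak_lpm": b.q_peak_lpm,
                "fio2_mean_percent": b.fio2_mean_percent,
            }
            for b in breaths
        ]
    ).to_csv(path, index=False)


def read_breaths(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["t_start_s", "t_end_s", "v_insp_ml", "v_exp_ml"])
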