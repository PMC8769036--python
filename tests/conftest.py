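import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dlitespiro as ds

settings.register_profile(
    "ci", derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def amb():
    """Ambient state of the bench protocol: 81800 Pa, 20 C."""
    return ds.AmbientConditions(81800.0, 293.15)


@pytest.fixture(scope="session")
def ideal_sensor():
    """Noise-free virtual sensor whose true Cd equals the assumed constant 0.7."""
    return ds.TrueSensorModel(cd_profile=ds.CdProfile.constant(0.7), noise_sd_pa=0.0)


@pytest.fixture(scope="session")
def variable_cd_sensor():
    """Virtual sensor with the flow-dependent Cd truth and default noise."""
    return ds.TrueSensorModel()


@pytest.fixture(scope="session")
def identity_table(amb, ideal_sensor):
    """Protocol calibration against the ideal sensor: dp_model == dps per row."""
    pairs = ds.generate_calibration_run(ideal_sensor, amb, seed=11)
    return ds.build_table(pairs, amb)


@pytest.fixture(scope="session")
def protocol_table(amb, variable_cd_sensor):
    """Protocol calibration against the variable-Cd truth (the realistic table)."""
    pairs = ds.generate_calibration_run(variable_cd_sensor, amb, seed=11)
    return ds.build_table(pairs, amb)


def random_monotone_table(rng: np.random.Generator, n: int) -> ds.CalibrationTable:
    """A structurally valid random lookup table (for search/interp properties)."""
    dps = np.sort(rng.uniform(0.05, 600.0, size=n))
    while np.any(np.diff(dps) <= 1e-6):
        dps = np.sort(rng.uniform(0.05, 600.0, size=n))
    dp_model = np.sort(rng.uniform(0.05, 600.0, size=n))
    return ds.CalibrationTable(
        dps=dps, dp_model=dp_model, flow_ref=np.arange(n, dtype=float),
        created_density_kg_m3=1.2,
    )


def scan_interpolate(table: ds.CalibrationTable, x: float) -> float:
    """Independent lookup oracle: linear scan for the bracket, then the
    two-point interpolation formula, with the same out-of-range anchors."""
    s = 1.0 if x >= 0 else -1.0
    x = abs(x)
    dps, dpm = table.dps, table.dp_model
    if x <= dps[0]:
        return s * (x / dps[0] * dpm[0])
    if x >= dps[-1]:
        slope = (dpm[-1] - dpm[-2]) / (dps[-1] - dps[-2])
        return s * (dpm[-1] + (x - dps[-1]) * slope)
    for k in range(table.n - 1):
        if dps[k] <= x <= dps[k + 1]:
            return s * (dpm[k] + (x - dps[k]) / (dps[k + 1] - dps[k]) * (dpm[k + 1] - dpm[k]))
    raise AssertionError("unreachable")
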