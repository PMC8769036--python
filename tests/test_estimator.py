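"""Dichotomic-search lookup, flow estimation, volume integration, breath segmentation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dlitespiro as ds
from dlitespiro.estimator import lookup_dp, max_search_steps

from conftest import random_monotone_table, scan_interpolate


class TestLookup:
    def test_exact_knot_returns_stored_value(self, protocol_table):
        for k in [0, 7, 23, 47]:
            res = lookup_dp(protocol_table, float(protocol_table.dps[k]))
            assert res.dp_pa == protocol_table.dp_model[k]
            assert not res.extrapolated

    def test_midway_target_returns_arithmetic_mean(self, protocol_table):
        k = 10
        x = (protocol_table.dps[k] + protocol_table.dps[k + 1]) / 2
        res = lookup_dp(protocol_table, float(x))
        assert res.dp_pa == pytest.approx(
            (protocol_table.dp_model[k] + protocol_table.dp_model[k + 1]) / 2, rel=1e-12
        )
        assert res.idx_hi == res.idx_lo + 1

    def test_worst_case_steps_on_48_row_table_is_six(self, protocol_table):
        targets = np.linspace(protocol_table.dps[0], protocol_table.dps[-1], 5000)
        steps = max(lookup_dp(protocol_table, float(x)).steps for x in targets)
        assert steps == 6

    def test_sign_is_mirrored_for_expiration(self, protocol_table):
        x = float(protocol_table.dps[20]) + 0.37
        pos = lookup_dp(protocol_table, x)
        neg = lookup_dp(protocol_table, -x)
        assert neg.dp_pa == -pos.dp_pa

    def test_below_range_anchors_at_physical_zero(self, protocol_table):
        x = float(protocol_table.dps[0]) / 2
        res = lookup_dp(protocol_table, x)
        assert res.dp_pa == pytest.approx(x / protocol_table.dps[0] * protocol_table.dp_model[0], rel=1e-12)
        assert not res.extrapolated
        assert lookup_dp(protocol_table, 0.0).dp_pa == 0.0

    def test_above_range_extrapolates_and_flags(self, protocol_table):
        x = float(protocol_table.dps[-1]) * 1.1
        res = lookup_dp(protocol_table, x)
        slope = (protocol_table.dp_model[-1] - protocol_table.dp_model[-2]) / (
            protocol_table.dps[-1] - protocol_table.dps[-2]
        )
        assert res.dp_pa == pytest.approx(
            protocol_table.dp_model[-1] + (x - protocol_table.dps[-1]) * slope, rel=1e-12
        )
        assert res.extrapolated

    @given(st.integers(0, 10_000), st.integers(2, 200))
    def test_matches_linear_scan_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        table = random_monotone_table(rng, n)
        for x in rng.uniform(-650.0, 650.0, size=5):
            assert lookup_dp(table, float(x)).dp_pa == pytest.approx(
                scan_interpolate(table, float(x)), rel=1e-12, abs=1e-12
            )

    @given(st.integers(0, 10_000), st.sampled_from([2, 3, 5, 17, 48, 100, 511, 1024]))
    def test_step_count_bound(self, seed, n):
        rng = np.random.default_rng(seed)
        table = random_monotone_table(rng, n)
        bound = int(np.ceil(np.log2(n))) + 1
        for x in rng.uniform(0.0, 650.0, size=5):
            assert lookup_dp(table, float(x)).steps <= bound
        assert max_search_steps(n) <= bound

    def test_interpolant_is_continuous_across_knots(self, protocol_table):
        eps = 1e-9
        for k in range(1, protocol_table.n - 1):
            x = float(protocol_table.dps[k])
            lo = lookup_dp(protocol_table, x - eps).dp_pa
            hi = lookup_dp(protocol_table, x + eps).dp_pa
            at = lookup_dp(protocol_table, x).dp_pa
            assert lo == pytest.approx(at, abs=1e-6)
            assert hi == pytest.approx(at, abs=1e-6)


class TestEstimateFlow:
    def test_zero_dps_gives_zero_flow(self, identity_table, amb):
        s = ds.VentilationSample(0.0, 0.0, 0.0, 21.0, amb)
        assert ds.estimate_flow(s, identity_table) == 0.0

    def test_identity_table_reduces_to_venturi_model(self, identity_table):
        # choose ambient so the density is exactly 1.2 kg/m3
        rho_target = 1.2
        m = ds.fio2_to_fractions(21.0).molar_mass_kg_per_mol()
        p = rho_target * 8.314 * 293.15 / m
        amb = ds.AmbientConditions(p, 293.15)
        s = ds.VentilationSample(0.0, 100.0, 0.0, 21.0, amb)
        q = ds.estimate_flow(s, identity_table)
        assert q == pytest.approx(31.45, abs=0.02)


class TestIntegrateVolume:
    def test_constant_flow(self):
        t = np.arange(0.0, 1.0 + 1e-12, 0.005)
        v = ds.integrate_volume(t, np.full_like(t, 6.0))  # 6 L/min = 100 mL/s
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(100.0, rel=1e-12)

    def test_zero_flow(self):
        t = np.linspace(0, 2, 50)
        assert np.all(ds.integrate_volume(t, np.zeros_like(t)) == 0.0)

    def test_linear_ramp_closed_form(self):
        t = np.linspace(0.0, 1.5, 301)
        q = 24.0 * t / 1.5  # ramp 0 -> 24 L/min over 1.5 s
        # triangle area: 1/2 * 400 mL/s * 1.5 s (trapezoid is exact on a line)
        assert ds.integrate_volume(t, q)[-1] == pytest.approx(300.0, rel=1e-12)

    def test_irregular_timestamps_accepted_non_monotone_rejected(self):
        t = np.array([0.0, 0.004, 0.011, 0.02])
        q = np.array([6.0, 6.0, 6.0, 6.0])
        assert ds.integrate_volume(t, q)[-1] == pytest.approx(2.0, rel=1e-12)
        with pytest.raises(ValueError):
            ds.integrate_volume(np.array([0.0, 0.01, 0.005]), np.zeros(3))

    @given(st.integers(0, 10_000))
    def test_matches_trapezoid_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.001, 0.01, size=80))
        q = rng.normal(0.0, 20.0, size=80)
        expected = np.trapezoid(q * 1000 / 60, t)
        assert ds.integrate_volume(t, q)[-1] == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestSegmentBreaths:
    def test_ideal_square_wave_recovers_tidal_volume(self):
        # VT=600 mL, 20 BPM, I:E 1:1 -> 24 L/min plateau, 1.5 s each phase
        dt = 0.005
        t = np.arange(0.0, 9.0, dt)
        q = np.where(np.mod(t, 3.0) < 1.5, 24.0, -24.0)
        breaths = ds.segment_breaths(t, q)
        assert len(breaths) == 3
        for b in breaths[:-1]:
            assert b.v_insp_ml == pytest.approx(600.0, rel=0.01)
            assert b.v_exp_ml == pytest.approx(600.0, rel=0.01)
            assert b.q_peak_lpm == 24.0

    def test_all_positive_flow_is_single_breath_with_no_expiration(self):
        t = np.linspace(0, 5, 500)
        breaths = ds.segment_breaths(t, np.full_like(t, 10.0))
        assert len(breaths) == 1
        assert breaths[0].v_exp_ml == 0.0
        assert breaths[0].v_insp_ml > 0

    def test_zero_signal_is_one_open_breath_with_zero_volumes(self):
        t = np.linspace(0, 5, 500)
        breaths = ds.segment_breaths(t, np.zeros_like(t))
        assert len(breaths) == 1
        assert breaths[0].v_insp_ml == 0.0 and breaths[0].v_exp_ml == 0.0

    def test_subthreshold_blips_do_not_trigger_breaths(self):
        t = np.arange(0.0, 4.0, 0.005)
        q = np.zeros_like(t)
        q[100] = 30.0  # single-sample spike, shorter than the hysteresis window
        breaths = ds.segment_breaths(t, q)
        assert len(breaths) == 1
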