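"""Virtual bench: waveform generator, virtual sensor, closed-loop runs."""
import numpy as np
import pytest

import dlitespiro as ds
from dlitespiro.bench import sensor_run


class TestWaveform:
    def test_inspiratory_plateau_is_vt_over_t_insp(self, amb):
        # 600 mL over 1.5 s inspiration -> 400 mL/s = 24 L/min
        sc = ds.VentilationScenario(vt_ml=600.0, bpm=20.0, ie_ratio=1.0, amb=amb)
        wf = ds.generate_waveform(sc)
        insp = wf["true_flow_lpm"] > 0
        # plateau carries a sub-percent discretization renormalization
        assert wf.loc[insp, "true_flow_lpm"].unique() == pytest.approx([24.0], rel=5e-3)

    def test_zero_tidal_volume_gives_zero_flow(self, amb):
        sc = ds.VentilationScenario(vt_ml=0.0, amb=amb)
        wf = ds.generate_waveform(sc)
        assert np.all(wf["true_flow_lpm"] == 0.0)

    @pytest.mark.parametrize("vt", [100.0, 400.0, 800.0])
    def test_per_breath_flow_integral_recovers_tidal_volume(self, amb, vt):
        sc = ds.VentilationScenario(vt_ml=vt, amb=amb, duration_s=9.0)
        wf = ds.generate_waveform(sc)
        breaths = ds.segment_breaths(wf["t_s"].to_numpy(), wf["true_flow_lpm"].to_numpy())
        assert len(breaths) == 3
        for b in breaths:
            assert b.v_insp_ml == pytest.approx(vt, rel=1e-3)
            assert b.v_exp_ml == pytest.approx(vt, rel=1e-3)

    def test_airway_pressure_starts_at_peep(self, amb):
        sc = ds.VentilationScenario(vt_ml=600.0, peep_cmh2o=5.0, amb=amb)
        wf = ds.generate_waveform(sc)
        assert wf["p_airway_pa"].iloc[0] == pytest.approx(5.0 * 98.0665)
        assert np.all(wf["p_airway_pa"] >= wf["p_airway_pa"].iloc[0] - 1e-9)

    def test_fio2_schedule_is_piecewise_constant(self, amb):
        sc = ds.VentilationScenario(
            vt_ml=600.0, amb=amb, duration_s=6.0, fio2_schedule=((0.0, 21.0), (3.0, 60.0))
        )
        wf = ds.generate_waveform(sc)
        assert np.all(wf.loc[wf["t_s"] < 3.0, "fio2_percent"] == 21.0)
        assert np.all(wf.loc[wf["t_s"] >= 3.0, "fio2_percent"] == 60.0)


class TestVirtualSensor:
    def test_zero_flow_zero_offset_reads_noise_only(self):
        model = ds.TrueSensorModel(noise_sd_pa=0.1)
        rng = np.random.default_rng(0)
        reads = ds.virtual_sensor_read(np.zeros(2000), model, 1.0, rng)
        assert abs(np.mean(reads)) < 0.01
        assert np.std(reads) == pytest.approx(0.1, rel=0.1)

    def test_constant_cd_noise_free_reduces_to_inverse_venturi(self, ideal_sensor):
        for q in [-30.0, -2.0, 5.0, 40.0]:
            dps = ds.virtual_sensor_read(q, ideal_sensor, 1.1)
            assert dps == pytest.approx(ds.dp_from_flow(q, 1.1), rel=1e-12)

    def test_cd_plateau_scales_dps_by_squared_ratio(self):
        plateau = ds.TrueSensorModel(noise_sd_pa=0.0)  # cd = 0.75 at 7.5 L/min
        const = ds.TrueSensorModel(cd_profile=ds.CdProfile.constant(0.7), noise_sd_pa=0.0)
        ratio = ds.virtual_sensor_read(7.5, plateau, 1.0) / ds.virtual_sensor_read(7.5, const, 1.0)
        assert ratio == pytest.approx((0.7 / 0.75) ** 2, rel=1e-12)

    def test_saturation_clips_reading(self):
        model = ds.TrueSensorModel(noise_sd_pa=0.0, saturation_pa=100.0)
        assert ds.virtual_sensor_read(80.0, model, 1.0) == 100.0
        assert ds.virtual_sensor_read(-80.0, model, 1.0) == -100.0

    def test_offset_shifts_reading(self):
        model = ds.TrueSensorModel(noise_sd_pa=0.0, offset_pa=0.5)
        assert ds.virtual_sensor_read(0.0, model, 1.0) == 0.5


class TestCalibrationRun:
    def test_default_grid_emits_48_pairs(self, variable_cd_sensor, amb):
        pairs = ds.generate_calibration_run(variable_cd_sensor, amb, seed=5)
        assert len(pairs) == 48

    def test_noise_free_ideal_pairs_calibrate_to_identity(self, identity_table):
        np.testing.assert_allclose(identity_table.dp_model, identity_table.dps, rtol=1e-12)

    def test_seeds_change_pairs_but_not_shape(self, variable_cd_sensor, amb):
        a = ds.generate_calibration_run(variable_cd_sensor, amb, seed=1)
        b = ds.generate_calibration_run(variable_cd_sensor, amb, seed=2)
        assert len(a) == len(b)
        assert any(pa != pb for pa, pb in zip(a, b))


class TestClosedLoop:
    def test_identical_seeds_are_bit_identical(self, variable_cd_sensor, protocol_table, amb):
        sc = ds.VentilationScenario(vt_ml=500.0, amb=amb, duration_s=6.0)
        a = ds.run_virtual_bench(sc, variable_cd_sensor, protocol_table, seed=7)
        b = ds.run_virtual_bench(sc, variable_cd_sensor, protocol_table, seed=7)
        assert a.equals(b)

    def test_noise_free_closed_loop_is_exact(self, ideal_sensor, identity_table, amb):
        sc = ds.VentilationScenario(vt_ml=600.0, amb=amb, duration_s=9.0)
        cmp_df = ds.run_virtual_bench(
            sc, ideal_sensor, identity_table, density_mode="per_sample", seed=3
        )
        assert len(cmp_df) == 3
        assert cmp_df["err_insp_rel"].abs().max() <= 1e-6
        assert cmp_df["err_exp_rel"].abs().max() <= 1e-6

    def test_variable_cd_truth_stays_inside_volume_margin(self, variable_cd_sensor, protocol_table, amb):
        worst = 0.0
        for vt in [100.0, 400.0, 800.0]:
            sc = ds.VentilationScenario(vt_ml=vt, amb=amb, duration_s=9.0)
            cmp_df = ds.run_virtual_bench(sc, variable_cd_sensor, protocol_table, seed=13)
            worst = max(worst, cmp_df["err_insp_rel"].abs().max())
        assert worst <= 0.10

    def test_fio2_steps_do_not_degrade_volume_when_density_corrected(self, variable_cd_sensor, protocol_table, amb):
        const = ds.VentilationScenario(vt_ml=600.0, amb=amb, duration_s=9.0)
        stepped = ds.VentilationScenario(
            vt_ml=600.0, amb=amb, duration_s=9.0,
            fio2_schedule=((0.0, 21.0), (3.0, 80.0), (6.0, 45.0)),
        )
        e_const = ds.run_virtual_bench(const, variable_cd_sensor, protocol_table, seed=4)["err_insp_rel"].abs().max()
        e_step = ds.run_virtual_bench(stepped, variable_cd_sensor, protocol_table, seed=4)["err_insp_rel"].abs().max()
        assert abs(e_step - e_const) < 0.02  # within the bench's noise envelope

    def test_sensor_run_is_seed_reproducible(self, variable_cd_sensor, amb):
        sc = ds.VentilationScenario(vt_ml=300.0, amb=amb, duration_s=3.0)
        assert sensor_run(sc, variable_cd_sensor, seed=9).equals(sensor_run(sc, variable_cd_sensor, seed=9))
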