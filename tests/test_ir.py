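"""IR profile extraction, fitting degree, diffusion width, isotherm deviation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from weldtherm import ir


def make_profile(x, T, time=0.0):
    return ir.ThermalProfile(np.asarray(x, float), np.asarray(T, float), time=time)


class TestThermalFrameValidation:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ir.ThermalFrame(np.array([[np.nan, 25.0]]), 0.1, 0.0)

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(ValueError):
            ir.ThermalFrame(np.full((2, 2), 25.0), 0.0, 0.0)


class TestProfileExtraction:
    def test_uniform_frame_constant_profile(self):
        frame = ir.ThermalFrame(np.full((10, 20), 25.0), 0.1, 0.0)
        prof = ir.profile_from_frames([frame], 0.0, row=5, edge_col=4)
        assert np.all(prof.temperature == 25.0)
        assert prof.distance_mm[0] == 0.0

    def test_linear_gradient_slope_recovered(self):
        pitch = 0.25  # mm / px
        cols = np.arange(40)
        a, b = 30.0, -0.8  # degC, degC/mm
        data = np.tile(a + b * cols * pitch, (8, 1))
        frame = ir.ThermalFrame(data, pitch, 0.0)
        prof = ir.profile_from_frames([frame], 0.0, row=3, edge_col=10)
        slope = np.polyfit(prof.distance_mm, prof.temperature, 1)[0]
        assert slope == pytest.approx(b, abs=1e-9)

    def test_time_outside_record_errors(self):
        frame = ir.ThermalFrame(np.full((4, 4), 25.0), 0.1, 0.0)
        with pytest.raises(ValueError):
            ir.profile_from_frames([frame], 5.0, row=0, edge_col=0)

    def test_nearest_frame_selected(self):
        frames = [
            ir.ThermalFrame(np.full((4, 4), float(i)), 0.1, i / 30.0) for i in range(10)
        ]
        prof = ir.profile_from_frames(frames, 4.4 / 30.0, row=1, edge_col=0)
        assert prof.temperature[0] == 4.0

    def test_outward_direction(self):
        data = np.tile(np.arange(10.0), (3, 1))
        frame = ir.ThermalFrame(data, 0.5, 0.0)
        left = ir.profile_from_frames([frame], 0.0, row=0, edge_col=5, outward=-1)
        assert list(left.temperature[:3]) == [5.0, 4.0, 3.0]


class TestFittingDegree:
    def test_identical_profiles_100(self):
        x = np.linspace(0, 8, 30)
        T = 50.0 - 3.0 * x
        rep = ir.fitting_degree(make_profile(x, T), make_profile(x, T))
        assert rep.fitting_degree == pytest.approx(100.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)

    def test_alternating_offset_hand_computed(self):
        # independent sums-of-squares oracle, computed inline
        x = np.linspace(1.0, 8.0, 10)
        sim = 50.0 - 25.0 / 8.0 * x  # spans ~25..47 degC
        noise = 0.5 * np.array([1, -1, 1, -1, 1, -1, 1, -1, 1, -1], float)
        meas = sim + noise
        ss_res = float(np.sum((meas - sim) ** 2))
        ss_tot = float(np.sum((meas - np.mean(meas)) ** 2))
        expected = 100.0 * (1.0 - ss_res / ss_tot)
        rep = ir.fitting_degree(make_profile(x, sim), make_profile(x, meas), window_start=1.0)
        assert rep.fitting_degree == pytest.approx(expected, abs=1e-9)

    def test_noisy_measurement_at_least_97(self, rng):
        x = np.linspace(0.0, 8.0, 200)
        sim = 50.0 - 25.0 / 8.0 * x  # span >= 20 degC
        meas = sim + rng.normal(0.0, 0.2, size=x.size)
        rep = ir.fitting_degree(make_profile(x, sim), make_profile(x, meas))
        assert rep.fitting_degree >= 97.0

    def test_constant_measurement_undefined(self):
        x = np.linspace(0, 5, 10)
        with pytest.raises(ir.UndefinedMetricError):
            ir.fitting_degree(make_profile(x, 30.0 - x), make_profile(x, np.full(10, 25.0)))

    def test_window_excludes_near_electrode_mismatch(self):
        x = np.linspace(0.0, 8.0, 81)
        sim = 50.0 - 3.0 * x
        meas = sim.copy()
        meas[x < 1.0] += 5.0  # near-edge deviation only
        rep = ir.fitting_degree(make_profile(x, sim), make_profile(x, meas), window_start=1.0)
        assert rep.fitting_degree == pytest.approx(100.0)

    def test_shift_invariance(self):
        x = np.linspace(0, 8, 40)
        sim = 45.0 - 2.0 * x
        meas = sim + np.sin(x)
        a = ir.fitting_degree(make_profile(x, sim), make_profile(x, meas))
        b = ir.fitting_degree(make_profile(x, sim + 7.0), make_profile(x, meas + 7.0))
        assert a.fitting_degree == pytest.approx(b.fitting_degree, abs=1e-9)

    def test_nrmse_method(self):
        x = np.linspace(0, 8, 40)
        sim = 45.0 - 2.0 * x
        rep = ir.fitting_degree(make_profile(x, sim), make_profile(x, sim), method="nrmse")
        assert rep.fitting_degree == pytest.approx(100.0)


class TestDiffusionWidth:
    def test_all_ambient_zero(self):
        x = np.linspace(0, 5, 20)
        assert ir.diffusion_width(make_profile(x, np.full(20, 25.0))) == 0.0

    def test_triangular_profile(self):
        # T falls 35 -> 25 over 0..5 mm; T - 25 > 0.5 until x = 4.75
        x = np.linspace(0.0, 5.0, 501)
        T = 35.0 - 2.0 * x
        assert ir.diffusion_width(make_profile(x, T), epsilon=0.5) == pytest.approx(
            4.75, abs=0.01
        )

    def test_everywhere_heated_full_span(self):
        x = np.linspace(0.0, 5.0, 50)
        assert ir.diffusion_width(make_profile(x, np.full(50, 30.0))) == pytest.approx(5.0)

    def test_nonpositive_epsilon_rejected(self):
        x = np.linspace(0, 5, 10)
        with pytest.raises(ValueError):
            ir.diffusion_width(make_profile(x, np.full(10, 30.0)), epsilon=0.0)


class TestDeviationRate:
    def test_paper_values(self):
        assert round(ir.deviation_rate(0.24, 4.32), 1) == 5.6

    def test_zero_deviation(self):
        assert ir.deviation_rate(0.0, 3.0) == 0.0

    def test_arithmetic(self):
        assert ir.deviation_rate(1.0, 10.0) == pytest.approx(10.0)

    def test_zero_width_errors(self):
        with pytest.raises(ZeroDivisionError):
            ir.deviation_rate(0.2, 0.0)

    @given(
        st.floats(min_value=0.01, max_value=10.0),
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, dev, width, c):
        a = ir.deviation_rate(dev, width)
        b = ir.deviation_rate(c * dev, c * width)
        assert a == pytest.approx(b, rel=1e-9)


class _FakeGeom:
    """Minimal geometry stand-in for isotherm tests."""

    def __init__(self, nx=40, ny=5, nz_tissue=4, nz_electrode=2, dx=0.2e-3):
        self.nx, self.ny = nx, ny
        self.nz_tissue, self.nz_electrode = nz_tissue, nz_electrode
        self.dx = dx

    @property
    def x_centers(self):
        return (np.arange(self.nx) + 0.5) * self.dx - self.nx * self.dx / 2.0


class TestIsothermDeviation:
    def _field(self, geom, offsets_mm):
        """Decreasing-in-|x| profile per tissue layer, crossing 40 degC at
        x = 2 mm + per-layer offset."""
        nz = geom.nz_tissue + 2 * geom.nz_electrode
        field = np.full((geom.nx, geom.ny, nz), 25.0)
        x_mm = geom.x_centers * 1e3
        for i, off in enumerate(offsets_mm):
            iz = geom.nz_electrode + i
            cross = 2.0 + off
            field[:, :, iz] = 60.0 - 20.0 / cross * np.abs(x_mm)[:, None]
        return field

    def test_z_uniform_zero(self):
        geom = _FakeGeom()
        field = self._field(geom, [0.0] * geom.nz_tissue)
        assert ir.isotherm_z_deviation(field, geom, 40.0) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_offset(self):
        geom = _FakeGeom()
        field = self._field(geom, [0.0, 0.1, 0.2, 0.3])
        dev = ir.isotherm_z_deviation(field, geom, 40.0)
        assert dev == pytest.approx(0.3, abs=0.02)

    def test_absent_isotherm_errors(self):
        geom = _FakeGeom()
        nz = geom.nz_tissue + 2 * geom.nz_electrode
        uniform = np.full((geom.nx, geom.ny, nz), 25.0)
        with pytest.raises(ir.IsothermAbsentError):
            ir.isotherm_z_deviation(uniform, geom, 40.0)


class TestProfileValidation:
    def test_decreasing_distance_rejected(self):
        with pytest.raises(ValueError):
            make_profile([0.0, 1.0, 0.5], [25.0, 26.0, 27.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_profile([0.0, 1.0], [25.0, 26.0, 27.0])


class TestExtractProfileDispatch:
    def test_dispatches_to_frames(self):
        frame = ir.ThermalFrame(np.full((6, 8), 25.0), 0.1, 0.0)
        prof = ir.extract_profile([frame], 0.0, row=2, edge_col=1)
        assert len(prof) == 7

    def test_dispatches_to_simulation(self, small_sim_config):
        from dataclasses import replace
        from weldtherm.solver import run_simulation

        cfg = replace(small_sim_config, end_time=0.2, checkpoint_times=(0.2,))
        res = run_simulation(cfg)
        prof = ir.extract_profile(res, 0.2)
        assert prof.distance_mm[0] >= 0.0
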