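"""Derivative signatures, marker detection and temperature correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meltid as m
from meltid.signatures import (analytic_derivative, derivative_signature,
                               detect_tm_marker, process_run, resample,
                               temperature_correct)


def make_curve(grid, values, channel="BS1"):
    return m.RawMeltCurve(grid.temperatures, values, channel)


def marker_segment(extra=()):
    return m.SegmentModel(components=list(extra), includes_tm_marker=True)


@pytest.fixture(scope="module")
def grid():
    return m.AcquisitionGrid(n_points=1024)


class TestDerivativeSignature:
    def test_constant_curve_gives_zero_signature(self, grid):
        sig = derivative_signature(make_curve(grid, np.full(grid.n_points, 2.0)))
        assert np.max(np.abs(sig.values)) < 1e-9

    def test_linear_curve_gives_constant_slope(self, grid):
        f = 5.0 - 0.2 * (grid.temperatures - 40.0)
        sig = derivative_signature(make_curve(grid, f))
        assert np.allclose(sig.values, -0.2, atol=1e-9)

    def test_single_transition_trough_at_tm(self, grid):
        # oracle: brute-force argmin of the closed-form derivative on the grid
        seg = m.SegmentModel([m.MeltComponent(75.0, 0.5, 1.0)])
        curve = m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0)
        sig = derivative_signature(curve)
        oracle = grid.temperatures[np.argmin(analytic_derivative(seg, grid))]
        trough = grid.temperatures[np.argmin(sig.values)]
        assert abs(trough - oracle) <= grid.step
        assert abs(trough - 75.0) <= grid.step

    def test_window_longer_than_curve_rejected(self):
        tiny = m.AcquisitionGrid(n_points=16)
        with pytest.raises(ValueError, match="shorter"):
            derivative_signature(make_curve(tiny, np.zeros(16)), window=21)

    def test_amplitude_scaling_is_linear(self, grid):
        seg = m.SegmentModel([m.MeltComponent(70.0, 0.5, 1.0)])
        curve = m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0)
        sig1 = derivative_signature(curve)
        curve.fluorescence = curve.fluorescence * 3.0
        sig3 = derivative_signature(curve)
        assert np.allclose(sig3.values, 3.0 * sig1.values, atol=1e-9)


class TestMarkerDetection:
    def test_marker_found_at_nominal_temperature(self, grid):
        curve = m.simulate_curve(marker_segment(), grid, m.NoiseModel.zero(), 0)
        tm = detect_tm_marker(derivative_signature(curve))
        assert abs(tm - m.MARKER_TM) <= grid.step

    def test_offset_shifts_detected_marker(self, grid):
        curve = m.simulate_curve(marker_segment(), grid, m.NoiseModel.zero(), 0,
                                 temperature_offset=0.8)
        tm = detect_tm_marker(derivative_signature(curve))
        assert abs(tm - 84.8) <= 2 * grid.step

    def test_marker_is_rightmost_not_deepest(self, grid):
        seg = marker_segment([m.MeltComponent(78.0, 0.4, 2.0)])  # deeper trough
        curve = m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0)
        tm = detect_tm_marker(derivative_signature(curve),
                              search_window=(77.0, 87.0))
        assert abs(tm - m.MARKER_TM) <= grid.step

    def test_flat_signature_has_no_marker(self, grid):
        sig = derivative_signature(make_curve(grid, np.full(grid.n_points, 1.0)))
        assert detect_tm_marker(sig) is None

    def test_bs2_input_rejected(self, grid):
        sig = derivative_signature(make_curve(grid, np.zeros(grid.n_points), "BS2"))
        with pytest.raises(ValueError, match="BS1"):
            detect_tm_marker(sig)


class TestTemperatureCorrection:
    def test_identity_shift_preserves_signature(self, grid):
        curve = m.simulate_curve(marker_segment(), grid, m.NoiseModel.zero(), 0)
        sig = derivative_signature(curve)
        sig.tm_detected = detect_tm_marker(sig)
        bs2 = derivative_signature(make_curve(grid, np.zeros(grid.n_points), "BS2"))
        c1, _ = temperature_correct(sig, bs2, reference_tm=sig.tm_detected)
        assert np.allclose(c1.values, sig.values, atol=1e-6)
        assert c1.corrected

    @pytest.mark.parametrize("offset", [-2.0, -0.8, 0.8, 2.0])
    def test_correction_recovers_injected_offset(self, grid, offset):
        seg = marker_segment([m.MeltComponent(70.0, 0.5, 1.0)])
        ref = m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0)
        ref_trough = grid.temperatures[np.argmin(
            derivative_signature(ref).values[:grid.n_points // 2])]
        shifted = m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0,
                                   temperature_offset=offset)
        sig = derivative_signature(shifted)
        sig.tm_detected = detect_tm_marker(sig)
        bs2 = derivative_signature(make_curve(grid, np.zeros(grid.n_points), "BS2"))
        corrected, _ = temperature_correct(sig, bs2)
        trough = grid.temperatures[np.argmin(corrected.values[:grid.n_points // 2])]
        assert abs(trough - ref_trough) <= grid.step

    def test_missing_marker_raises(self, grid):
        sig = derivative_signature(make_curve(grid, np.zeros(grid.n_points)))
        bs2 = derivative_signature(make_curve(grid, np.zeros(grid.n_points), "BS2"))
        with pytest.raises(ValueError, match="marker"):
            temperature_correct(sig, bs2)

    def test_same_shift_applied_to_both_channels(self, grid):
        seg1 = marker_segment([m.MeltComponent(70.0, 0.5, 1.0)])
        seg2 = m.SegmentModel([m.MeltComponent(60.0, 0.5, 1.0)])
        off = 1.2
        c1 = m.simulate_curve(seg1, grid, m.NoiseModel.zero(), 0, temperature_offset=off)
        c2 = m.simulate_curve(seg2, grid, m.NoiseModel.zero(), 0, "BS2",
                              temperature_offset=off)
        s1, s2 = derivative_signature(c1), derivative_signature(c2)
        s1.tm_detected = detect_tm_marker(s1)
        cs1, cs2 = temperature_correct(s1, s2)
        t2 = grid.temperatures[np.argmin(cs2.values)]
        assert abs(t2 - 60.0) <= 2 * grid.step

    def test_edge_regions_zero_filled(self, grid):
        curve = m.simulate_curve(marker_segment(), grid, m.NoiseModel.zero(), 0)
        sig = derivative_signature(curve)
        sig.tm_detected = m.MARKER_TM - 2.0  # forces a +2 degC shift
        bs2 = derivative_signature(make_curve(grid, np.zeros(grid.n_points), "BS2"))
        corrected, _ = temperature_correct(sig, bs2)
        n_edge = int(1.9 / grid.step)
        assert np.all(corrected.values[:n_edge] == 0.0)


class TestResample:
    def test_identity_on_own_grid(self, grid):
        seg = m.SegmentModel([m.MeltComponent(70.0, 0.5, 1.0)])
        sig = derivative_signature(m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0))
        out = resample(sig, grid)
        assert np.allclose(out.values, sig.values)

    def test_downsample_error_small_on_smooth_signal(self):
        fine = m.AcquisitionGrid(n_points=4076)
        coarse = m.AcquisitionGrid(n_points=1019)
        seg = m.SegmentModel([m.MeltComponent(70.0, 0.5, 1.0)])
        sig = m.Signature(fine, analytic_derivative(seg, fine), "BS1")
        out = resample(sig, coarse)
        truth = analytic_derivative(seg, coarse)
        err = np.max(np.abs(out.values - truth))
        assert err < 1e-3 * np.ptp(truth)

    def test_upsample_then_downsample_round_trip(self, grid):
        seg = m.SegmentModel([m.MeltComponent(70.0, 0.5, 1.0)])
        sig = derivative_signature(m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0))
        fine = m.AcquisitionGrid(n_points=2 * grid.n_points - 1)
        back = resample(resample(sig, fine), grid)
        assert np.max(np.abs(back.values - sig.values)) < 1e-6


class TestProcessRun:
    @given(offset=st.floats(-2.0, 2.0))
    @settings(max_examples=10, deadline=None)
    def test_correction_recovers_random_offsets(self, offset):
        grid = m.AcquisitionGrid(n_points=1024)
        panel = m.build_default_panel(1)
        noise = m.NoiseModel(0.0, 0.0, 0.0, 0.0)
        run = m.simulate_run(panel[0], run_id="r", specimen_id="s", replicate=1,
                             sample_condition="fresh", grid=grid, noise=noise,
                             seed=0, pinned_failure="none")
        ref = process_run(run)
        run.bs1_curve = m.simulate_curve(panel[0].bs1, grid, noise, 0,
                                         temperature_offset=offset)
        run.bs2_curve = m.simulate_curve(panel[0].bs2, grid, noise, 0, "BS2",
                                         temperature_offset=offset)
        out = process_run(run)
        assert out.tm_ok
        half = grid.n_points // 2
        t_ref = grid.temperatures[np.argmin(ref.bs1.values[:half])]
        t_out = grid.temperatures[np.argmin(out.bs1.values[:half])]
        assert abs(t_out - t_ref) <= grid.step * (1 + 1e-9)

    def test_shift_equivariance_of_derivative(self):
        grid = m.AcquisitionGrid(n_points=1024)
        seg = m.SegmentModel([m.MeltComponent(65.0, 0.5, 1.0)])
        a = derivative_signature(m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0))
        b = derivative_signature(m.simulate_curve(seg, grid, m.NoiseModel.zero(), 0,
                                                  temperature_offset=1.0))
        ta = grid.temperatures[np.argmin(a.values)]
        tb = grid.temperatures[np.argmin(b.values)]
        assert abs((tb - ta) - 1.0) <= grid.step
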