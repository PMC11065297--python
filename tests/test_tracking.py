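"""Frame-stack tracking: geometry detection, onset, tongue tip, units."""

import numpy as np
import pytest

from oomech.simulate import generate_curve, render_frame_stack, RenderGeometry
from oomech.tracking import (FrameStack, crop_roi, select_start_frame,
                             measure_zona_thickness, measure_pipette_inner_diameter,
                             track_aspirated_zona, compress_time_vector,
                             to_micrometers, extract_curve, NoMotionError,
                             DetectionError)


class TestCropRoi:
    def test_full_frame_is_identity(self, rendered):
        _, stack, _ = rendered
        h, w = stack.shape
        out = crop_roi(stack, (0, 0, h, w))
        assert np.array_equal(out.frames, stack.frames)

    def test_out_of_bounds_rejected(self, rendered):
        _, stack, _ = rendered
        h, w = stack.shape
        for roi in [(0, 0, h + 1, w), (-1, 0, h, w), (0, 0, 0, w)]:
            with pytest.raises(ValueError):
                crop_roi(stack, roi)

    def test_crop_then_track_matches_track(self, rendered):
        # depths are measured from the pipette tip, so a crop that keeps
        # the pipette in view must not change them
        _, stack, _ = rendered
        h, w = stack.shape
        cropped = crop_roi(stack, (30, 40, h - 60, w - 40))
        d_full = extract_curve(stack).depths
        d_crop = extract_curve(cropped).depths
        assert np.allclose(d_full, d_crop, atol=0.51)


class TestGeometryMeasurements:
    def test_pipette_inner_diameter(self, rendered):
        _, stack, truth = rendered
        px = measure_pipette_inner_diameter(stack.frames[0])
        assert abs(px - truth["lumen_px"]) <= 1

    def test_diameter_invariant_to_intensity_rescale(self, rendered):
        _, stack, _ = rendered
        f = stack.frames[0]
        assert (measure_pipette_inner_diameter(0.5 * f + 0.2)
                == measure_pipette_inner_diameter(f))

    def test_zona_thickness(self, rendered):
        _, stack, truth = rendered
        scale = truth["um_per_px"]
        zona = measure_zona_thickness(stack.frames[0], scale)
        assert zona == pytest.approx(15.0, abs=1.1 * scale)

    def test_zona_linear_in_scale(self, rendered):
        _, stack, _ = rendered
        z1 = measure_zona_thickness(stack.frames[0], 0.5)
        z2 = measure_zona_thickness(stack.frames[0], 1.0)
        assert z2 == pytest.approx(2 * z1)

    def test_blank_frame_is_detection_error(self):
        blank = np.full((64, 64), 0.2, dtype=np.float32)
        with pytest.raises(DetectionError):
            measure_pipette_inner_diameter(blank)
        with pytest.raises(DetectionError):
            measure_zona_thickness(blank, 0.5)


class TestStartFrameAndTracking:
    def test_start_is_frame_before_motion(self, default_params, force_spec):
        curve = generate_curve(default_params, force_spec.F0, noise_sd=0.0, seed=0)
        stack, truth = render_frame_stack(curve, n_pre_frames=10, seed=1)
        assert truth["onset_index"] == 10
        assert select_start_frame(stack, motion_threshold=1.0) == 9

    def test_static_stack_raises_no_motion(self):
        from oomech.tracking import AspirationCurve
        flat = AspirationCurve(times=np.arange(8) / 70.0, depths=np.zeros(8))
        stack, _ = render_frame_stack(flat, seed=2)
        with pytest.raises(NoMotionError):
            select_start_frame(stack)

    def test_tracked_positions_match_truth(self, rendered):
        _, stack, truth = rendered
        pos = track_aspirated_zona(stack, start=0)
        assert np.max(np.abs(pos - truth["tip_positions_px"])) <= 1

    def test_initial_position_is_zona_thickness(self, rendered):
        # Fig-style convention: the resting tip sits one zona thickness
        # into the pipette, the "initial aspiration depth"
        _, stack, truth = rendered
        pos = track_aspirated_zona(stack, start=0)
        zona_px = measure_zona_thickness(stack.frames[0], 1.0)
        assert abs(pos[0] - zona_px) <= 1

    def test_zero_motion_frames_constant(self):
        from oomech.tracking import AspirationCurve
        flat = AspirationCurve(times=np.arange(8) / 70.0,
                               depths=np.full(8, 4.0))
        stack, _ = render_frame_stack(flat, noise_sd=0.0, seed=0)
        pos = track_aspirated_zona(stack, start=0)
        assert np.ptp(pos[5:]) == 0


class TestTimeAndUnits:
    def test_compress_keeps_moved_frames(self):
        pos = np.concatenate([np.full(6, 30.0), 30 + np.arange(1, 41) * 2.0])
        times, kept = compress_time_vector(pos, frame_rate=70.0)
        assert times[0] == 0.0
        assert len(kept) == 36           # clipped to the 0.5 s window
        assert times[-1] == pytest.approx(0.5)
        assert kept[0] == 32.0           # first moved frame retained

    def test_compress_identity_when_all_moving(self):
        pos = 30 + np.arange(1, 13) * 3.0
        times, kept = compress_time_vector(pos, frame_rate=70.0)
        assert np.array_equal(kept, pos)
        assert times[-1] == pytest.approx(11 / 70)

    def test_to_micrometers_conversion(self):
        # 50 um lumen measured as 100 px -> 0.5 um/px; 30 px -> 15 um
        factor = 50.0 / 100.0
        assert to_micrometers(np.array([30.0]), factor)[0] == pytest.approx(15.0)
        assert np.array_equal(to_micrometers(np.arange(4.0), 1.0), np.arange(4.0))
        with pytest.raises(ValueError):
            to_micrometers(np.arange(4.0), 0.0)


class TestClosedLoop:
    def test_render_track_recovers_curve(self, rendered):
        curve, stack, truth = rendered
        out = extract_curve(stack)
        n = min(len(out.depths), len(curve.depths))
        err = np.abs(out.depths[:n] - np.asarray(curve.depths)[:n])
        assert err.max() <= 1.0 * truth["um_per_px"] + 1e-9
        assert np.all((out.times >= 0) & (out.times <= 0.5))

    def test_scale_invariance_of_micrometer_depths(self, default_params, force_spec):
        # halving the pixel scale (finer sampling) leaves um depths intact
        curve = generate_curve(default_params, force_spec.F0, noise_sd=0.0, seed=6)
        g_fine = RenderGeometry(um_per_px=0.4, image_shape=(300, 440))
        s1, _ = render_frame_stack(curve, seed=1)
        s2, _ = render_frame_stack(curve, geometry=g_fine, seed=1)
        d1, d2 = extract_curve(s1).depths, extract_curve(s2).depths
        n = min(len(d1), len(d2))
        assert np.allclose(d1[:n], d2[:n], atol=0.5 + 0.4)
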