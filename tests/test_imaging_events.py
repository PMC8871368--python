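"""Ratio computation, moving-average subtraction and event detection."""

import dataclasses

import numpy as np
import pytest

from prehear.imaging_events import (DetectionConfig, ImagingStack, Rect,
                                    compute_ratio, default_baseline_roi,
                                    detect_events, measure_baseline,
                                    moving_average_subtract, summarize_events)
from prehear.synth import generate_imaging_stack


def make_stack(frames, px=2.0, dt=1.0, modality="dic"):
    return ImagingStack(np.asarray(frames, float), px, dt, modality)


class TestRatio:
    def test_identical_channels_give_unity(self):
        s = make_stack(np.full((8, 4, 4), 500.0))
        r = compute_ratio(s, s)
        assert np.allclose(r.frames, 1.0)

    def test_pixelwise_division(self):
        a = make_stack(np.full((8, 2, 2), 200.0))
        b = make_stack(np.full((8, 2, 2), 100.0))
        assert np.allclose(compute_ratio(a, b).frames, 2.0)

    def test_zero_denominator_masked(self):
        a = make_stack(np.full((8, 2, 2), 200.0))
        d = np.full((8, 2, 2), 100.0)
        d[3, 0, 0] = 0.0
        r = compute_ratio(a, make_stack(d))
        assert np.isnan(r.frames[3, 0, 0])
        assert np.isfinite(r.frames[3, 1, 1])

    def test_shape_mismatch_rejected(self):
        a = make_stack(np.zeros((8, 4, 4)) + 1)
        b = make_stack(np.zeros((8, 4, 5)) + 1)
        with pytest.raises(ValueError):
            compute_ratio(a, b)


class TestMovingAverageSubtract:
    def test_constant_stack_gives_zero(self):
        d = moving_average_subtract(make_stack(np.full((20, 3, 3), 77.0)), 5)
        assert np.allclose(d.frames[5:], 0.0)
        assert np.isnan(d.frames[:5]).all()

    def test_step_response(self):
        """A step of +s appears as +s, then fades as the window catches up."""
        f = np.full((30, 2, 2), 100.0)
        f[12:] += 10.0
        d = moving_average_subtract(make_stack(f), 5).frames[:, 0, 0]
        assert d[12] == pytest.approx(10.0)
        assert d[13] == pytest.approx(10.0 - 10.0 / 5)
        assert d[17] == pytest.approx(0.0)
        assert np.allclose(d[18:], 0.0)

    def test_single_frame_impulse(self):
        f = np.full((30, 2, 2), 100.0)
        f[12] += 8.0
        d = moving_average_subtract(make_stack(f), 5).frames[:, 0, 0]
        assert d[12] == pytest.approx(8.0)
        assert d[13] == pytest.approx(-8.0 / 5)

    def test_linearity(self, rng):
        f = rng.normal(1000, 30, size=(25, 6, 6))
        d1 = moving_average_subtract(make_stack(f), 5).frames
        d2 = moving_average_subtract(make_stack(3.0 * f + 50.0), 5).frames
        assert np.allclose(d2[5:], 3.0 * d1[5:])

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            moving_average_subtract(make_stack(np.zeros((6, 2, 2)) + 1), 6)


class TestBaseline:
    def test_constant_roi(self):
        s = make_stack(np.full((10, 20, 20), 100.0))
        assert measure_baseline(s, Rect(0, 10, 0, 10)) == 100.0

    def test_noisy_roi_mean(self, rng):
        f = rng.normal(50.0, 5.0, size=(50, 20, 20))
        s = make_stack(f)
        assert measure_baseline(s, Rect(0, 20, 0, 40)) == pytest.approx(50.0, abs=0.5)

    def test_roi_outside_field_rejected(self):
        s = make_stack(np.full((10, 8, 8), 1.0))
        with pytest.raises(ValueError):
            measure_baseline(s, Rect(0, 100, 0, 100))


class TestDetection:
    def test_pure_noise_no_events(self, small_wave_preset):
        stack, _ = generate_imaging_stack(small_wave_preset, 3)
        base = measure_baseline(stack, default_baseline_roi(stack))
        delta = moving_average_subtract(stack, 5)
        events = detect_events(delta, base, DetectionConfig())
        assert len(events) == 0

    @pytest.mark.parametrize("area", [200.0, 600.0])
    def test_injected_event_area_recovered(self, small_wave_preset, area):
        stack, truth = generate_imaging_stack(
            small_wave_preset, 4,
            forced_events=[{"area_um2": area, "cx_um": 64.0, "cy_um": 64.0,
                            "t0": 20}])
        base = measure_baseline(stack, default_baseline_roi(stack))
        delta = moving_average_subtract(stack, 5)
        events = detect_events(delta, base, DetectionConfig())
        assert len(events) == 1
        assert events["area_um2"].iloc[0] == pytest.approx(
            truth["events"][0]["area_um2"], rel=0.15)

    def test_event_below_min_area_dropped(self, small_wave_preset):
        stack, _ = generate_imaging_stack(
            small_wave_preset, 4,
            forced_events=[{"area_um2": 30.0, "cx_um": 64.0, "cy_um": 64.0,
                            "t0": 20}])
        base = measure_baseline(stack, default_baseline_roi(stack))
        delta = moving_average_subtract(stack, 5)
        events = detect_events(delta, base, DetectionConfig(min_area_um2=50.0))
        assert len(events) == 0

    def test_detection_monotone_in_amplitude(self, small_wave_preset):
        """Raising an event's amplitude never removes it."""
        detected = []
        for amp in (0.18, 0.3, 0.5):
            p = dataclasses.replace(small_wave_preset, event_amplitude=amp)
            stack, _ = generate_imaging_stack(
                p, 6, forced_events=[{"area_um2": 400.0, "cx_um": 64.0,
                                      "cy_um": 64.0, "t0": 20}])
            base = measure_baseline(stack, default_baseline_roi(stack))
            delta = moving_average_subtract(stack, 5)
            detected.append(len(detect_events(delta, base, DetectionConfig())))
        assert detected == sorted(detected)
        assert detected[-1] == 1


class TestSummary:
    def test_frequency_arithmetic(self, small_wave_preset):
        stack, _ = generate_imaging_stack(
            small_wave_preset, 7,
            forced_events=[{"area_um2": 400.0, "cx_um": 64.0, "cy_um": 64.0,
                            "t0": 10 + 12 * k} for k in range(4)])
        base = measure_baseline(stack, default_baseline_roi(stack))
        delta = moving_average_subtract(stack, 5)
        events = detect_events(delta, base, DetectionConfig())
        s = summarize_events(events, 400.0)
        assert s.frequency_hz == pytest.approx(s.n_events / 400.0)

    def test_zero_events(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["area_um2", "in_analysis_roi"])
        s = summarize_events(empty, 100.0)
        assert s.frequency_hz == 0.0 and s.mean_area_um2 == 0.0
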