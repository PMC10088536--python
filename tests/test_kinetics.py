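"""Intensity traces, inclusion rule, uptake fitting and flow derivation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebusdepot.io import VideoSequence, roi_bounds
from ebusdepot.kinetics import (
    LN20,
    IntensityTrace,
    detect_onset,
    fit_uptake,
    flow_rate,
    intensity_variation,
    mean_cone_trace,
    moving_average,
    passes_inclusion,
    uptake_model,
)
from ebusdepot.segmentation import compute_background
from ebusdepot.simulate import synthetic_trace


def make_video(frames, fps=10.0):
    return VideoSequence(frames=np.asarray(frames, dtype=float), frame_rate=fps)


def full_roi(shape):
    return roi_bounds(shape, (shape[0] // 2, shape[1] // 2), px_per_cm=max(shape), side_cm=1.0)


class TestIntensityVariation:
    def test_identical_frames_give_zero(self):
        video = make_video(np.full((5, 8, 8), 0.4))
        trace = intensity_variation(video, full_roi((8, 8)))
        np.testing.assert_allclose(trace.values, 0.0)

    def test_doubling_gives_100_percent(self):
        frames = np.stack([np.full((8, 8), 0.2), np.full((8, 8), 0.4)])
        trace = intensity_variation(make_video(frames), full_roi((8, 8)))
        assert trace.values[1] == pytest.approx(100.0)

    def test_matches_hand_computed_means(self):
        rng = np.random.default_rng(3)
        frames = rng.random((6, 10, 10))
        video = make_video(frames)
        roi = roi_bounds((10, 10), (5, 5), px_per_cm=4.0, side_cm=1.0)
        trace = intensity_variation(video, roi)
        sub = frames[(slice(None),) + roi.slices]
        expected = 100.0 * (sub.mean(axis=(1, 2)) - sub[0].mean()) / sub[0].mean()
        np.testing.assert_allclose(trace.values, expected, atol=1e-9)

    def test_zero_reference_frame_fails(self):
        frames = np.zeros((3, 8, 8))
        frames[1:] = 0.5
        with pytest.raises(ValueError, match="degenerate"):
            intensity_variation(make_video(frames), full_roi((8, 8)))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(0)
        frames = rng.random((5, 8, 8)) + 0.1
        roi = full_roi((8, 8))
        t1 = intensity_variation(make_video(frames), roi)
        t2 = intensity_variation(make_video(frames * k), roi)
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-9, atol=1e-9)


class TestMovingAverage:
    def test_constant_unchanged(self):
        trace = IntensityTrace(times=np.arange(50) / 10.0, values=np.full(50, 3.3))
        out = moving_average(trace, 1.0)
        np.testing.assert_allclose(out.values, 3.3)
        assert out.smoothing_window == 1.0

    def test_sinusoid_at_window_frequency_suppressed(self):
        fps, window = 30.0, 1.0
        t = np.arange(int(20 * fps)) / fps
        trace = IntensityTrace(times=t, values=np.sin(2 * math.pi * t / window))
        out = moving_average(trace, window)
        interior = slice(int(fps), -int(fps))
        assert np.max(np.abs(out.values[interior])) <= 0.02

    def test_single_sample_window_is_identity(self):
        trace = IntensityTrace(times=np.arange(20) / 10.0, values=np.random.default_rng(0).random(20))
        np.testing.assert_array_equal(moving_average(trace, 0.1).values, trace.values)

    def test_too_small_window_rejected(self):
        trace = IntensityTrace(times=np.arange(20) / 10.0, values=np.zeros(20))
        with pytest.raises(ValueError):
            moving_average(trace, 0.01)


class TestInclusion:
    def test_boundary_is_strictly_above(self):
        trace = IntensityTrace(times=np.arange(5.0), values=np.array([0, 5, 20.0, 10, 0]), smoothing_window=1.0)
        included, peak = passes_inclusion(trace, 20.0)
        assert not included and peak == 20.0

    def test_above_threshold_included(self):
        trace = IntensityTrace(times=np.arange(5.0), values=np.array([0, 5, 20.1, 10, 0]), smoothing_window=1.0)
        assert passes_inclusion(trace, 20.0)[0]

    def test_unsmoothed_trace_warns_but_applies(self):
        trace = IntensityTrace(times=np.arange(5.0), values=np.full(5, 30.0))
        with pytest.warns(UserWarning, match="unsmoothed"):
            included, _ = passes_inclusion(trace)
        assert included


class TestMeanConeTrace:
    def test_frame_equal_to_background_gives_zero(self):
        video = make_video(np.full((10, 8, 8), 0.3))
        trace = mean_cone_trace(video, np.full((8, 8), 0.3), t0=0.2)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)
        assert trace.times[0] == pytest.approx(0.0)

    def test_noiseless_simulator_matches_kinetic_law(self, noiseless_sim):
        config, video, truth = noiseless_sim
        bg = compute_background(video, config.t0)
        trace = mean_cone_trace(video, bg.image, config.t0)
        expected = config.c + config.a * (1 - np.exp(-config.b * trace.times))
        np.testing.assert_allclose(trace.values, expected, atol=1e-6)

    def test_onset_at_last_frame_fails(self):
        video = make_video(np.full((10, 8, 8), 0.3))
        with pytest.raises(ValueError, match="post-onset"):
            mean_cone_trace(video, np.full((8, 8), 0.3), t0=0.9)

    def test_empty_cone_fails(self):
        video = VideoSequence(
            frames=np.full((5, 8, 8), 0.3), frame_rate=10.0, cone_mask=np.zeros((8, 8), bool)
        )
        with pytest.raises(ValueError, match="cone"):
            mean_cone_trace(video, np.full((8, 8), 0.3), t0=0.1)


class TestFitUptake:
    def test_noiseless_recovery_is_exact(self):
        trace = synthetic_trace(a=10.0, b=0.6, c=0.5, noise_sd=0.0, duration=20.0, frame_rate=30.0)
        fit = fit_uptake(trace)
        assert fit.a == pytest.approx(10.0, rel=1e-6)
        assert fit.b == pytest.approx(0.6, rel=1e-6)
        assert fit.c == pytest.approx(0.5, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_delta_t_closed_form(self):
        trace = synthetic_trace(a=1.0, b=0.6, noise_sd=0.0, duration=20.0)
        fit = fit_uptake(trace)
        assert fit.delta_t == pytest.approx(math.log(20) / 0.6, rel=1e-6)
        assert fit.delta_t * fit.b == pytest.approx(LN20, rel=1e-12)

    def test_too_few_samples_rejected(self):
        trace = IntensityTrace(times=np.arange(4) / 10.0, values=np.arange(4.0))
        with pytest.raises(ValueError, match="5 samples"):
            fit_uptake(trace)

    def test_grid_search_oracle_agreement(self):
        # dense grid over (a, b, c) on a short noisy trace: the constrained
        # least-squares fit must be at least as good as the best grid point
        # and land within one grid step of it
        rng = np.random.default_rng(42)
        trace = synthetic_trace(a=5.0, b=0.4, c=1.0, noise_sd=0.25, duration=10.0, frame_rate=2.0, rng=rng)
        t, y = trace.times, trace.values
        a_grid = np.linspace(3.0, 7.0, 41)
        b_grid = np.linspace(0.1, 1.0, 46)
        c_grid = np.linspace(0.0, 2.0, 41)
        best = (np.inf, None)
        for a in a_grid:
            for b in b_grid:
                pred_ab = a * (1 - np.exp(-b * t))
                for c in c_grid:
                    ssr = float(np.sum((y - c - pred_ab) ** 2))
                    if ssr < best[0]:
                        best = (ssr, (a, b, c))
        fit = fit_uptake(trace)
        ssr_fit = float(np.sum((y - uptake_model(t, fit.a, fit.b, fit.c)) ** 2))
        assert ssr_fit <= best[0] + 1e-9
        ga, gb, gc = best[1]
        assert abs(fit.a - ga) <= a_grid[1] - a_grid[0]
        assert abs(fit.b - gb) <= b_grid[1] - b_grid[0]
        assert abs(fit.c - gc) <= c_grid[1] - c_grid[0]

    def test_noisy_recovery_within_ten_percent(self):
        ok = 0
        for seed in range(50):
            trace = synthetic_trace(a=1.0, b=0.15, noise_sd=0.05, duration=60.0, frame_rate=30.0, rng=seed)
            fit = fit_uptake(trace)
            if abs(fit.b - 0.15) / 0.15 <= 0.10:
                ok += 1
        assert ok >= 47


class TestFlowRate:
    @pytest.mark.parametrize(
        "volume,delta_t,expected",
        [(10.0, 5.10, 1.9608), (8.0, 16.63, 0.4811)],
    )
    def test_flow_rate_arithmetic(self, volume, delta_t, expected):
        fit = fit_uptake(synthetic_trace(a=1.0, b=LN20 / delta_t, noise_sd=0.0, duration=4 * delta_t))
        flow = flow_rate(volume, fit)
        assert flow.q_ml_per_s == pytest.approx(expected, abs=2e-4)

    def test_flow_vanishes_for_long_injections(self):
        fit_fast = fit_uptake(synthetic_trace(a=1.0, b=1.0, noise_sd=0.0, duration=20.0))
        fit_slow = fit_uptake(synthetic_trace(a=1.0, b=0.05, noise_sd=0.0, duration=200.0))
        assert flow_rate(8.0, fit_slow).q_ml_per_s < flow_rate(8.0, fit_fast).q_ml_per_s

    def test_invalid_volume(self):
        fit = fit_uptake(synthetic_trace(a=1.0, b=0.5, noise_sd=0.0, duration=20.0))
        with pytest.raises(ValueError):
            flow_rate(0.0, fit)


def test_detect_onset_backtracks_to_minimum():
    fps = 10.0
    t = np.arange(int(20 * fps)) / fps
    values = np.where(t < 5.0, 0.5, 40.0 * (1 - np.exp(-(t - 5.0))))
    trace = IntensityTrace(times=t, values=values, smoothing_window=1.0)
    assert detect_onset(trace) == pytest.approx(5.0, abs=0.3)


def test_detect_onset_requires_sustained_rise():
    t = np.arange(100) / 10.0
    trace = IntensityTrace(times=t, values=np.zeros(100), smoothing_window=1.0)
    with pytest.raises(ValueError, match="onset"):
        detect_onset(trace)
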