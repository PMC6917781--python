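"""Chamber segmentation, growth traces, logistic fits and egg phenotypes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormchip import chamber, imgen
from wormchip.chamber import (
    GrowthTrace,
    SegmentationConfig,
    egg_phenotypes,
    estimate_background,
    fit_growth_sigmoid,
    growth_trace,
    segment_worms,
)
from wormchip.io_core import BRIGHTFIELD, FrameStack


class TestBackground:
    def test_static_scene_background_equals_frame(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=0, n_frames=5, noise_sd=0.0)
        series, _ = imgen.render_chamber_series(spec, [])
        bg = estimate_background(series.stack)
        assert np.array_equal(bg, series.stack.frames[0].astype(np.float32))

    def test_moving_worms_recover_empty_chamber(self, logistic_chamber):
        spec, _, series, truth = logistic_chamber
        bg = estimate_background(series.stack)
        deviation = np.abs(bg - truth.empty_frame)
        assert deviation.max() < 3 * spec.noise_sd

    def test_too_few_frames_rejected(self):
        stack = FrameStack(np.zeros((2, 8, 8), np.uint16), [0, 30], BRIGHTFIELD, 3.2)
        with pytest.raises(ValueError, match=">= 3 frames"):
            estimate_background(stack)


class TestSegmentation:
    def test_single_worm_area_within_5_percent(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=2, n_frames=6, noise_sd=0.0)
        series, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(initial_area=2000)]
        )
        area = segment_worms(series.stack.frames[3], truth.empty_frame).sum()
        assert abs(area - 2000) / 2000 < 0.05

    def test_frame_equal_to_background_yields_empty_mask(self):
        bg = np.full((64, 64), 12000.0, dtype=np.float32)
        assert segment_worms(bg, bg).sum() == 0

    def test_translation_invariance_within_2_percent(self):
        # identical synthetic worm blob at two positions over a flat background
        bg = np.full((200, 260), 24000.0, dtype=np.float32)
        rr = np.arange(200)[:, None]
        cc = np.arange(260)[None, :]

        def frame(center):
            blob = ((rr - center[0]) / 12) ** 2 + ((cc - center[1]) / 40) ** 2 <= 1
            out = bg.copy()
            out[blob] = 9000.0
            return out

        a = segment_worms(frame((100, 100)), bg).sum()
        b = segment_worms(frame((110, 100)), bg).sum()
        assert abs(a - b) / a < 0.02

    def test_noise_robustness_under_3_percent_of_range(self):
        worms = [imgen.WormSpec(initial_area=2500)]
        areas = []
        for noise in (0.0, 0.03 * 65535):
            spec = imgen.SceneSpec.for_chamber(rng_seed=8, n_frames=6, noise_sd=noise)
            series, truth = imgen.render_chamber_series(spec, worms)
            areas.append(segment_worms(series.stack.frames[2], truth.empty_frame).sum())
        assert abs(areas[1] - areas[0]) / areas[0] < 0.05


class TestGrowthTrace:
    def test_normalization_identity_exact(self, logistic_chamber):
        _, _, series, _ = logistic_chamber
        trace = growth_trace(series.stack, n_worms=3)
        assert np.array_equal(trace.normalized_area * 3, trace.total_area)

    def test_tracks_generator_truth_within_5_percent(self, logistic_chamber):
        _, _, series, truth = logistic_chamber
        trace = growth_trace(series.stack, n_worms=3)
        rel = np.abs(trace.total_area - truth.total_area) / truth.total_area
        assert rel.max() < 0.05

    def test_flat_trace_for_constant_scene(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=4, n_frames=6, noise_sd=0.0)
        series, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(initial_area=2200)]
        )
        trace = growth_trace(series.stack, n_worms=1, background=truth.empty_frame)
        assert np.ptp(trace.total_area) / trace.total_area.mean() < 0.02

    def test_invalid_worm_count(self, logistic_chamber):
        _, _, series, _ = logistic_chamber
        with pytest.raises(ValueError, match="n_worms"):
            growth_trace(series.stack, n_worms=0)


class TestLogisticFit:
    def test_parameter_recovery_within_1_percent(self):
        growth = imgen.LogisticGrowth(lower=1400, upper=6200, rate=0.007, midpoint=650)
        times = np.arange(49) * 30.0
        trace = GrowthTrace(times=times, total_area=np.asarray(growth.area(times)), n_worms=1)
        fit = fit_growth_sigmoid(trace)
        assert fit.converged and not fit.degenerate
        for got, true in [
            (fit.lower, growth.lower),
            (fit.upper, growth.upper),
            (fit.rate, growth.rate),
            (fit.midpoint, growth.midpoint),
        ]:
            assert abs(got - true) / abs(true) < 0.01

    def test_flat_trace_flagged_degenerate(self):
        trace = GrowthTrace(times=np.arange(10) * 30.0, total_area=np.full(10, 3000.0), n_worms=1)
        fit = fit_growth_sigmoid(trace)
        assert fit.degenerate and fit.rate == 0.0

    def test_noisy_midpoint_within_one_frame(self):
        rng = np.random.default_rng(17)
        growth = imgen.LogisticGrowth(lower=1500, upper=6000, rate=0.008, midpoint=700)
        times = np.arange(49) * 30.0
        y = np.asarray(growth.area(times))
        y = y + rng.normal(0.0, 0.03 * (y.max() - y.min()), size=y.shape)
        fit = fit_growth_sigmoid(GrowthTrace(times=times, total_area=y, n_worms=1))
        assert abs(fit.midpoint - 700.0) <= 30.0

    def test_too_few_points_rejected(self):
        trace = GrowthTrace(times=np.arange(4) * 30.0, total_area=np.arange(4.0), n_worms=1)
        with pytest.raises(ValueError, match=">= 6"):
            fit_growth_sigmoid(trace)


class TestEggPhenotypes:
    def test_worked_example(self):
        pheno = egg_phenotypes([0, 0, 1, 3, 5], np.arange(5) * 30.0, n_worms=2)
        assert pheno.t_first_egg == 60.0
        assert pheno.eggs_at_first == 1
        assert pheno.eggs_at_first_plus_1h == 5
        assert pheno.release_rate == pytest.approx(1.0)  # (5-1)/2h/2 worms

    def test_no_egg_laying_flag(self):
        pheno = egg_phenotypes(np.zeros(6), np.arange(6) * 30.0, n_worms=4)
        assert pheno.no_egg_laying
        assert np.isnan(pheno.t_first_egg)

    def test_generator_schedule_recovered_exactly(self):
        events = (600.0, 630.0, 660.0, 840.0)
        spec = imgen.SceneSpec.for_chamber(rng_seed=1, n_frames=40, noise_sd=0.0)
        _, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(egg_events=events)], keep_masks=False
        )
        pheno = egg_phenotypes(truth.egg_count, truth.times, n_worms=1)
        assert pheno.t_first_egg == 600.0
        assert pheno.eggs_at_first == 1
        assert pheno.eggs_at_first_plus_1h == 3  # events at 600/630/660 within +1 h
        assert pheno.release_rate == pytest.approx((3 - 1) / 2.0)

    def test_decreasing_counts_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            egg_phenotypes([0, 2, 1], np.arange(3) * 30.0, n_worms=1)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=5), min_size=5, max_size=12),
        n_worms=st.integers(min_value=1, max_value=30),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariants_hold_for_any_cumulative_series(self, counts, n_worms):
        cumulative = np.cumsum(counts).astype(float)
        times = np.arange(len(cumulative)) * 30.0
        pheno = egg_phenotypes(cumulative, times, n_worms)
        if pheno.no_egg_laying:
            assert cumulative[-1] == 0
        else:
            assert pheno.eggs_at_first_plus_1h >= pheno.eggs_at_first
            assert pheno.release_rate >= 0
            assert pheno.t_first_egg in times
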