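"""Embryo viability, event detection, masks and normalized intensity."""

import numpy as np
import pytest

from conftest import TRAP_PATCH, trap_scene_spec
from wormchip import embryo, imgen
from wormchip.embryo import (
    MotionTrace,
    analyze_trap_series,
    build_masks,
    classify_viability,
    detect_events,
    hatch_aligned_trace,
    motion_trace,
    normalized_intensity,
)
from wormchip.geometry import TrapGeometry
from wormchip.io_core import FLUORESCENCE, FrameStack


class TestMasks:
    def test_masks_equal_area_and_positive(self, geometry):
        pair = build_masks(geometry, TRAP_PATCH)
        assert pair.embryo_mask.sum() == pair.background_mask.sum()
        assert pair.embryo_mask.sum() > 0

    def test_masks_avoid_rendered_walls(self, geometry, alive_trap_series):
        _, truth = alive_trap_series
        pair = build_masks(geometry, TRAP_PATCH)
        assert not (pair.embryo_mask & truth.wall_mask).any()

    def test_zero_shift_rejected(self, geometry):
        from dataclasses import replace

        degenerate = replace(geometry, mask_shift=0)
        with pytest.raises(ValueError, match="mask_shift"):
            build_masks(degenerate, TRAP_PATCH)


class TestMotionAndViability:
    def test_dead_render_is_motionless_and_dead(self, geometry, dead_trap_series):
        series, _ = dead_trap_series
        pair = build_masks(geometry, TRAP_PATCH)
        trace = motion_trace(series.bf_trap, pair.embryo_mask)
        assert np.all(trace.energy == 0.0)
        assert not classify_viability(trace)

    def test_two_identical_frames_zero_energy(self, geometry):
        pair = build_masks(geometry, TRAP_PATCH)
        frames = np.full((3, TRAP_PATCH, TRAP_PATCH), 500, dtype=np.uint16)
        stack = FrameStack(frames, [0, 10, 20], "brightfield", 0.8)
        trace = motion_trace(stack, pair.embryo_mask)
        assert np.all(trace.energy == 0.0)

    def test_motion_energy_rises_at_twitch_onset(self, geometry, alive_trap_series):
        series, truth = alive_trap_series
        pair = build_masks(geometry, TRAP_PATCH)
        trace = motion_trace(series.bf_trap, pair.embryo_mask)
        pre = trace.energy[trace.times < truth.t_twitch]
        moving = trace.energy[(trace.times >= truth.t_twitch) & (trace.times < truth.t_hatch)]
        assert moving.min() >= 3 * np.median(pre[:3])

    def test_pure_noise_classified_dead(self, geometry):
        rng = np.random.default_rng(0)
        frames = rng.normal(20000, 600, size=(30, TRAP_PATCH, TRAP_PATCH))
        stack = FrameStack(
            np.clip(frames, 0, 65535).astype(np.uint16),
            np.arange(30) * 10.0,
            "brightfield",
            0.8,
        )
        pair = build_masks(TrapGeometry(), TRAP_PATCH)
        assert not classify_viability(motion_trace(stack, pair.embryo_mask))

    @pytest.mark.parametrize("seed", range(10))
    def test_alive_across_seeds_at_3_percent_noise(self, geometry, seed):
        spec = trap_scene_spec(500 + seed, n_frames=70, noise_sd=0.03 * 65535)
        es = imgen.EmbryoSpec(
            alive=True, t_twitch=250.0, t_hatch=640.0,
            intensity_ramp=imgen.IntensityRamp(1.0, 0.0, 1.0),
        )
        series, _ = imgen.render_trap_series(
            spec, es, patch_size=TRAP_PATCH, channels=("brightfield",)
        )
        pair = build_masks(geometry, TRAP_PATCH)
        assert classify_viability(motion_trace(series.bf_trap, pair.embryo_mask))


class TestEventDetection:
    def test_events_within_one_frame(self, geometry, alive_trap_series):
        series, truth = alive_trap_series
        pair = build_masks(geometry, TRAP_PATCH)
        trace = motion_trace(series.bf_trap, pair.embryo_mask)
        events = detect_events(trace, series.bf_trap, pair.embryo_mask)
        assert abs(events.t_twitch - truth.t_twitch) <= 10.0
        assert abs(events.t_hatch - truth.t_hatch) <= 10.0
        assert events.duration == events.t_hatch - events.t_twitch

    def test_unhatched_render_flagged(self, geometry):
        spec = trap_scene_spec(31, n_frames=40)
        es = imgen.EmbryoSpec(
            alive=True, t_twitch=150.0, t_hatch=2000.0,  # beyond the window
            intensity_ramp=imgen.IntensityRamp(1.0, 0.0, 1.0),
        )
        series, _ = imgen.render_trap_series(spec, es, patch_size=TRAP_PATCH)
        record = analyze_trap_series(series, geometry)
        assert record.alive and not record.hatched
        assert np.isnan(record.duration)
        # unhatched: trace left unaligned (original acquisition times)
        assert record.trace_times is not None
        assert record.trace_times.min() >= 0.0

    def test_dead_embryo_never_produces_events(self, geometry, dead_trap_series):
        series, _ = dead_trap_series
        record = analyze_trap_series(series, geometry)
        assert not record.alive
        assert np.isnan(record.t_twitch) and np.isnan(record.t_hatch)


class TestNormalizedIntensity:
    def _patches(self, geometry, embryo_value, background_value):
        pair = build_masks(geometry, TRAP_PATCH)
        trap = np.full((2, TRAP_PATCH, TRAP_PATCH), float(background_value))
        trap[:, pair.embryo_mask] = embryo_value
        inc = np.full((2, TRAP_PATCH, TRAP_PATCH), float(background_value))
        times = [0.0, 10.0]
        return (
            FrameStack(trap, times, FLUORESCENCE, 0.8),
            FrameStack(inc, times, FLUORESCENCE, 0.8),
            pair,
        )

    def test_ratio_of_double_is_two(self, geometry):
        trap, inc, pair = self._patches(geometry, 2400.0, 1200.0)
        np.testing.assert_array_equal(normalized_intensity(trap, inc, pair), 2.0)

    def test_gain_invariance_exact(self, geometry):
        trap, inc, pair = self._patches(geometry, 1800.0, 1200.0)
        base = normalized_intensity(trap, inc, pair)
        from dataclasses import replace

        for gain in (2.0, 3.7):
            scaled = normalized_intensity(
                replace(trap, frames=trap.frames * gain),
                replace(inc, frames=inc.frames * gain),
                pair,
            )
            if gain == 2.0:  # power-of-two gain: bit-exact
                assert np.array_equal(scaled, base)
            else:
                np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_zero_background_rejected(self, geometry):
        trap, inc, pair = self._patches(geometry, 100.0, 0.0)
        with pytest.raises(ValueError, match="positive"):
            normalized_intensity(trap, inc, pair)

    def test_ramp_render_tracks_truth_within_3_percent(self, geometry, alive_trap_series):
        series, truth = alive_trap_series
        pair = build_masks(geometry, TRAP_PATCH)
        i_norm = normalized_intensity(series.fl_trap, series.fl_incubator, pair)
        present = series.fl_trap.times < truth.t_hatch
        rel = np.abs(i_norm[present] - truth.normalized_intensity[present])
        assert (rel / truth.normalized_intensity[present]).max() < 0.03


class TestHatchAlignment:
    def test_truncation_and_realignment(self):
        times = np.arange(73) * 10.0
        values = np.linspace(1.0, 1.6, 73)
        t_aligned, v = hatch_aligned_trace(times, values, t_hatch=600.0)
        assert len(t_aligned) == 61
        assert t_aligned[-1] == 0.0
        assert np.all(t_aligned <= 0.0)
        assert np.all(np.diff(v) > 0)  # monotone ramp stays monotone

    def test_full_pipeline_trace_has_no_posthatch_samples(self, geometry, alive_trap_series):
        series, _ = alive_trap_series
        record = analyze_trap_series(series, geometry)
        assert record.hatched
        assert record.trace_times.max() == 0.0
        assert np.all(record.trace > 0)
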