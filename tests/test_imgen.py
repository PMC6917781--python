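"""Generator contracts: determinism, truth-render consistency, noise
separation, and event encoding."""

import numpy as np
import pytest

from conftest import TRAP_PATCH, trap_scene_spec
from wormchip import imgen
from wormchip.geometry import TrapGeometry


class TestChamberRender:
    def test_constant_worm_truth_area_is_exact(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=0, n_frames=6, noise_sd=0.0)
        series, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(initial_area=2000)]
        )
        assert np.all(truth.total_area == 2000)

    def test_truth_equals_union_mask_pixel_count(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=7, n_frames=8, noise_sd=300.0)
        growth = imgen.LogisticGrowth(lower=1500, upper=6000, rate=0.01, midpoint=120)
        series, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(growth=growth) for _ in range(3)]
        )
        counts = truth.masks.reshape(truth.masks.shape[0], -1).sum(axis=1)
        assert np.array_equal(counts, truth.total_area)

    def test_egg_schedule_bookkeeping(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=1, n_frames=23, noise_sd=0.0)
        series, truth = imgen.render_chamber_series(
            spec, [imgen.WormSpec(egg_events=(600.0, 630.0))]
        )
        expected = np.where(spec.times < 600, 0, np.where(spec.times < 630, 1, 2))
        assert np.array_equal(truth.egg_count, expected)

    def test_truth_invariant_to_noise(self):
        worms = [imgen.WormSpec(initial_area=1800)]
        results = []
        for noise in (0.0, 900.0):
            spec = imgen.SceneSpec.for_chamber(rng_seed=5, n_frames=5, noise_sd=noise)
            _, truth = imgen.render_chamber_series(spec, worms)
            results.append(truth)
        assert np.array_equal(results[0].total_area, results[1].total_area)
        assert np.array_equal(results[0].masks, results[1].masks)

    def test_determinism(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=9, n_frames=4)
        a, _ = imgen.render_chamber_series(spec, [imgen.WormSpec()])
        b, _ = imgen.render_chamber_series(spec, [imgen.WormSpec()])
        assert np.array_equal(a.stack.frames, b.stack.frames)

    def test_centroid_outside_chamber_rejected(self):
        spec = imgen.SceneSpec.for_chamber(rng_seed=0, n_frames=3)
        path = np.full((3, 2), -50.0)
        with pytest.raises(ValueError, match="footprint"):
            imgen.render_chamber_series(spec, [imgen.WormSpec(centroid_path=path)])


class TestSerpentineRender:
    def test_full_serpentine_has_regular_truth(self):
        spec = imgen.SceneSpec(rng_seed=0, noise_sd=0.0, n_frames=2)
        _, truth = imgen.render_serpentine(spec)
        assert len(truth.trap_coords) == 25
        spacing = np.diff(truth.trap_coords[:, 1])
        assert np.all(spacing == spacing[0])
        assert np.unique(truth.trap_coords[:, 0]).size == 1

    def test_single_unit(self):
        spec = imgen.SceneSpec(rng_seed=0, noise_sd=0.0, n_frames=2)
        stack, truth = imgen.render_serpentine(spec, n_traps=1)
        assert len(truth.trap_coords) == 1
        h, w = stack.frame_shape
        row, col = truth.trap_coords[0]
        assert abs(col - w // 2) <= 1 and abs(row - h // 2) <= 1

    def test_truth_independent_of_noise(self):
        geom = TrapGeometry()
        coords = []
        for noise in (0.0, 8.0):
            spec = imgen.SceneSpec(rng_seed=4, noise_sd=noise, n_frames=2)
            _, truth = imgen.render_serpentine(spec, geom)
            coords.append(truth.trap_coords)
        assert np.array_equal(coords[0], coords[1])


class TestTrapRender:
    def test_dead_embryo_is_static(self, dead_trap_series):
        series, truth = dead_trap_series
        frames = series.bf_trap.frames
        assert np.all(frames == frames[0])  # noise-free dead render: no change
        fl = series.fl_trap.frames
        assert np.all(fl == fl[0])
        assert truth.t_twitch is None and truth.t_hatch is None

    def test_event_times_map_to_frames(self, alive_trap_series):
        series, truth = alive_trap_series
        frames = series.bf_trap.frames
        # truth events at frames 30 and 72 for a 10-min cadence
        assert truth.t_twitch == 300.0 and truth.t_hatch == 720.0
        spec = trap_scene_spec(11, n_frames=80, noise_sd=0.0)
        embryo_spec = imgen.EmbryoSpec(
            alive=True, t_twitch=300.0, t_hatch=720.0,
            intensity_ramp=imgen.IntensityRamp(1.0, 0.001, 1.6),
        )
        clean, _ = imgen.render_trap_series(
            spec, embryo_spec, patch_size=TRAP_PATCH, channels=("brightfield",)
        )
        f = clean.bf_trap.frames
        # no texture displacement before twitching: frames 0..29 identical
        assert all(np.array_equal(f[i], f[0]) for i in range(1, 30))
        # every transition while twitching moves the texture
        assert all(not np.array_equal(f[i], f[i + 1]) for i in range(30, 71))
        # object absent from the hatch frame onward: empty trap, static
        assert all(np.array_equal(f[i], f[72]) for i in range(73, 80))
        assert not np.array_equal(f[71], f[72])

    def test_baseline_at_background_gives_unit_truth(self):
        spec = trap_scene_spec(2, n_frames=10, noise_sd=0.0)
        es = imgen.EmbryoSpec(
            alive=True, t_twitch=30.0, t_hatch=1000.0,
            intensity_ramp=imgen.IntensityRamp(baseline=1.0, slope=0.0, plateau=1.0),
        )
        _, truth = imgen.render_trap_series(spec, es, patch_size=TRAP_PATCH)
        assert truth.normalized_intensity[0] == pytest.approx(1.0, abs=1e-3)

    def test_determinism_and_noise_separation(self):
        es = imgen.EmbryoSpec(
            alive=True, t_twitch=200.0, t_hatch=600.0,
            intensity_ramp=imgen.IntensityRamp(1.0, 0.0005, 1.4),
        )
        spec = trap_scene_spec(21, n_frames=65)
        a, ta = imgen.render_trap_series(spec, es, patch_size=TRAP_PATCH)
        b, tb = imgen.render_trap_series(spec, es, patch_size=TRAP_PATCH)
        assert np.array_equal(a.bf_trap.frames, b.bf_trap.frames)
        assert np.array_equal(a.fl_trap.frames, b.fl_trap.frames)
        quiet, tq = imgen.render_trap_series(
            trap_scene_spec(21, n_frames=65, noise_sd=0.0), es, patch_size=TRAP_PATCH
        )
        np.testing.assert_allclose(tq.normalized_intensity, ta.normalized_intensity)
        assert not np.array_equal(quiet.bf_trap.frames, a.bf_trap.frames)

    def test_embryo_spec_invariants(self):
        with pytest.raises(ValueError, match="t_twitch < t_hatch"):
            imgen.EmbryoSpec(alive=True, t_twitch=500.0, t_hatch=400.0)
        with pytest.raises(ValueError, match="twitch_amplitude"):
            imgen.EmbryoSpec(alive=False, twitch_amplitude=2.0)
        with pytest.raises(ValueError, match="non-decreasing"):
            imgen.IntensityRamp(baseline=1.5, slope=0.0, plateau=1.0)


class TestLarvaRender:
    def test_straight_larva_bounding_length(self):
        spec = imgen.SceneSpec(rng_seed=0, noise_sd=0.0, n_frames=2)
        _, _, truth = imgen.render_larva(spec, 250.0, 12.0, 1.5, curvature=0.0)
        cols = np.flatnonzero(truth.larva_mask.any(axis=0))
        extent = cols[-1] - cols[0] + 1
        assert 312 <= extent <= 313  # 250 µm / 0.8 µm/px with cap geometry

    def test_gfp_at_background_gives_unit_truth(self):
        spec = imgen.SceneSpec(rng_seed=0, noise_sd=0.0, n_frames=2)
        _, _, truth = imgen.render_larva(spec, 250.0, 12.0, 1.0)
        assert truth.mean_intensity_norm == pytest.approx(1.0, abs=0.02)

    def test_seed_contract(self):
        t = []
        stacks = []
        for seed in (1, 2):
            spec = imgen.SceneSpec(rng_seed=seed, noise_sd=200.0, n_frames=2)
            bf, fl, truth = imgen.render_larva(spec, 250.0, 12.0, 2.0, curvature=0.0)
            t.append(truth)
            stacks.append(bf.frames)
        assert t[0].length_um == t[1].length_um
        assert t[0].diameter_um == t[1].diameter_um
        assert np.array_equal(t[0].larva_mask, t[1].larva_mask)
        assert not np.array_equal(stacks[0], stacks[1])

    def test_mask_count_matches_truth_area(self, curved_larva):
        _, _, truth = curved_larva
        assert truth.larva_mask.sum() == truth.area


class TestPresets:
    def test_scene_spec_invariants(self):
        with pytest.raises(ValueError):
            imgen.SceneSpec(n_frames=1)
        with pytest.raises(ValueError):
            imgen.SceneSpec(pixel_size=0.0)
        with pytest.raises(ValueError):
            imgen.SceneSpec(frame_interval=-1.0)

    def test_continuous_60_has_no_embryos(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="suppressed"):
            imgen.draw_embryo_spec(rng, "MET", 60)
        with pytest.raises(ValueError, match="suppressed"):
            imgen.draw_embryo_arm(rng, "MET", 60, 5)

    @pytest.mark.parametrize(
        "condition,dose,pct",
        [("OMT", 15, 4.0), ("MET", 15, 6.0), ("MET", 30, 9.0), ("OMT", 30, 7.0), ("OMT", 60, 5.0)],
    )
    def test_arm_durations_center_on_preset(self, condition, dose, pct):
        rng = np.random.default_rng(123)
        specs = imgen.draw_embryo_arm(rng, condition, dose, 30)
        durations = np.array([e.t_hatch - e.t_twitch for e in specs])
        expected = 420.0 * (1.0 + pct / 100.0)
        assert durations.mean() == pytest.approx(expected, abs=1.5)
        assert all(e.t_twitch < e.t_hatch for e in specs)
        assert all(180.0 <= e.t_twitch < 300.0 for e in specs)

    def test_scene_spec_yaml_roundtrip(self, tmp_path):
        spec = imgen.SceneSpec(rng_seed=4, pixel_size=3.2, n_frames=7)
        path = tmp_path / "scene.yaml"
        imgen.save_scene_spec(spec, path)
        assert imgen.load_scene_spec(path) == spec
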