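"""End-to-end synthetic study protocols.

These functions wire generator → analysis → statistics into the standard
validation studies of the package: timing-contrast recovery for the
doxycycline treatment arms, trap-localization accuracy, embryo event
recovery, and the type-I calibration of the group comparison.  They are used
both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import embryo as embryo_mod
from . import imgen
from . import traps as traps_mod
from .geometry import TrapGeometry
from .io_core import BRIGHTFIELD

__all__ = [
    "round_percent",
    "timing_contrast_study",
    "trap_localization_study",
    "event_recovery_study",
    "type_i_calibration",
    "EventRecovery",
]

#: Patch scale used for the simulation studies (the analysis is patch-size
#: agnostic; 128 px comfortably contains the trap unit and keeps a 20 ×
#: 60-embryo study within minutes on one CPU).
STUDY_PATCH_SIZE = 128
STUDY_NOISE_SD = 300.0
STUDY_N_FRAMES = 80  # 10-min cadence → events up to ~790 min observable


def round_percent(p: float) -> int:
    """Round half away from zero, the integer-percent reporting convention."""
    return int(np.floor(p + 0.5)) if p >= 0 else -int(np.floor(-p + 0.5))


def _detect_duration(
    spec: imgen.SceneSpec,
    embryo_spec: imgen.EmbryoSpec,
    patch_size: int,
) -> float:
    series, _ = imgen.render_trap_series(
        spec, embryo_spec, patch_size=patch_size, channels=(BRIGHTFIELD,)
    )
    record = embryo_mod.analyze_trap_series(series)
    if not (record.alive and record.hatched):
        return float("nan")
    return record.duration


def timing_contrast_study(
    condition: str,
    dose: int,
    base_seed: int,
    n_per_arm: int = 30,
    n_replicates: int = 20,
    patch_size: int = STUDY_PATCH_SIZE,
    noise_sd: float = STUDY_NOISE_SD,
    n_frames: int = STUDY_N_FRAMES,
) -> list[float]:
    """Percent change in mean twitching-to-hatching duration, treated versus
    control, measured end-to-end through the imaging pipeline.

    Each replicate renders ``n_per_arm`` control and treated trap series from
    the (condition, dose) preset, detects each embryo's events from the
    brightfield patches, and contrasts the arm means.  Returns the raw
    percent change per replicate (round with :func:`round_percent` for the
    reporting convention).
    """
    percents: list[float] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), rep]))
        means: dict[str, float] = {}
        for label, (arm_cond, arm_dose) in (
            ("control", ("CNT", 0)),
            ("treated", (condition, dose)),
        ):
            specs = imgen.draw_embryo_arm(rng, arm_cond, arm_dose, n_per_arm)
            durations = []
            for es in specs:
                scene = imgen.SceneSpec(
                    rng_seed=int(rng.integers(0, 2**31)),
                    pixel_size=0.8,
                    frame_interval=10.0,
                    n_frames=n_frames,
                    noise_sd=noise_sd,
                )
                d = _detect_duration(scene, es, patch_size)
                if np.isfinite(d):
                    durations.append(d)
            means[label] = float(np.mean(durations))
        percents.append(100.0 * (means["treated"] - means["control"]) / means["control"])
    return percents


@dataclass
class EventRecovery:
    t_twitch_true: float
    t_hatch_true: float
    t_twitch_detected: float
    t_hatch_detected: float
    alive_detected: bool
    hatched_detected: bool


def event_recovery_study(
    base_seed: int,
    n_embryos: int = 50,
    frame_interval: float = 10.0,
    patch_size: int = STUDY_PATCH_SIZE,
    noise_sd: float = STUDY_NOISE_SD,
) -> list[EventRecovery]:
    """Twitch/hatch recovery on alive embryos with randomized event times.

    Twitch onset uniform in [180, 420] min and duration uniform in
    [400, 500] min; the stack is sized so every hatch is observable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 9001]))
    n_frames = int(np.ceil((420.0 + 500.0) / frame_interval)) + 3
    out = []
    for _ in range(n_embryos):
        t_twitch = float(rng.uniform(180.0, 420.0))
        duration = float(rng.uniform(400.0, 500.0))
        es = imgen.EmbryoSpec(
            alive=True,
            t_twitch=t_twitch,
            t_hatch=t_twitch + duration,
            intensity_ramp=imgen.IntensityRamp(1.0, 0.001, 1.6),
        )
        scene = imgen.SceneSpec(
            rng_seed=int(rng.integers(0, 2**31)),
            pixel_size=0.8,
            frame_interval=frame_interval,
            n_frames=n_frames,
            noise_sd=noise_sd,
        )
        series, _ = imgen.render_trap_series(
            scene, es, patch_size=patch_size, channels=(BRIGHTFIELD,)
        )
        record = embryo_mod.analyze_trap_series(series)
        out.append(
            EventRecovery(
                t_twitch_true=t_twitch,
                t_hatch_true=t_twitch + duration,
                t_twitch_detected=record.t_twitch,
                t_hatch_detected=record.t_hatch,
                alive_detected=record.alive,
                hatched_detected=record.hatched,
            )
        )
    return out


def trap_localization_study(
    base_seed: int,
    n_seeds: int = 10,
    noise_sd: float = 0.0,
    geometry: TrapGeometry | None = None,
) -> list[dict]:
    """Localize every unit of a full serpentine across rendering seeds.

    Returns one record per seed with the detected site count, the number of
    true units, and the maximum localization error against render truth
    (NaN when counts differ).
    """
    geom = geometry or TrapGeometry()
    out = []
    for i in range(n_seeds):
        spec = imgen.SceneSpec(
            rng_seed=int(base_seed) + i, noise_sd=noise_sd, n_frames=2
        )
        stack, truth = imgen.render_serpentine(spec, geom)
        result = traps_mod.locate_traps(stack.frames[0], geom)
        n_true = len(truth.trap_coords)
        record = {"n_detected": len(result.sites), "n_true": n_true, "max_error_px": float("nan")}
        if len(result.sites) == n_true:
            errors = [
                float(np.hypot(s.intersection[0] - r, s.intersection[1] - c))
                for s, (r, c) in zip(result.sites, truth.trap_coords)
            ]
            record["max_error_px"] = max(errors)
        out.append(record)
    return out


def type_i_calibration(
    base_seed: int,
    n_simulations: int = 100,
    n_per_group: int = 20,
    alpha: float = 0.05,
) -> float:
    """False-positive rate of the one-way group comparison under the null.

    Both groups are drawn from the same normal distribution; returns the
    fraction of simulations with p < alpha (should calibrate to ≈ alpha).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 606]))
    hits = 0
    for _ in range(n_simulations):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        _, p = sps.f_oneway(a, b)
        hits += p < alpha
    return hits / n_simulations
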