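"""Embryo viability, twitching/hatching detection and normalized intensity.

The trapped embryo is analyzed entirely inside a pair of masks derived from
the device geometry: an embryo mask covering the egg footprint in the trap
(eroded so it never touches PDMS walls) and the identical footprint shifted
into the incubator lumen as the fluorescence background reference.

* **Viability** uses brightfield motion energy — the mean absolute
  frame-to-frame difference over the embryo mask.  An embryo is alive when
  the energy exceeds ``k``× the noise floor (median of the first
  transitions) in ``m`` consecutive transitions; dead embryos are static.
* **Twitching onset** is the first time of that sustained exceedance.
* **Hatching** is detected as the L1 leaving the trap: the first frame whose
  dark-foreground occupancy of the embryo mask drops below 30 % of the
  pre-hatch median.  Timing resolution is one frame interval (10 min); no
  sub-frame interpolation is attempted.
* **Normalized intensity** divides the mean embryo-mask fluorescence by the
  mean background-mask fluorescence, per frame; traces are aligned so t = 0
  is the hatching event and post-hatch samples are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .geometry import TrapGeometry
from .imgen import TrapPatchSeries
from .io_core import FrameStack

__all__ = [
    "MotionTrace",
    "MaskPair",
    "EventDetection",
    "EmbryoRecord",
    "build_masks",
    "motion_trace",
    "classify_viability",
    "detect_events",
    "normalized_intensity",
    "hatch_aligned_trace",
    "analyze_trap_series",
]

#: Exceedance factor over the noise floor for motion detection.
MOTION_FACTOR = 3.0
#: Number of consecutive exceeding transitions required.
MOTION_RUN = 2
#: Transitions used for the noise-floor estimate.
NOISE_FLOOR_TRANSITIONS = 3
#: Occupancy fraction of the pre-hatch median below which the trap is empty.
HATCH_OCCUPANCY_FRACTION = 0.3


@dataclass
class MotionTrace:
    """Per-transition motion energy: mean |frame_t − frame_{t−1}| over the
    embryo mask, in grayscale units.  ``times`` are the later frame of each
    transition, so the trace has ``n_frames − 1`` samples."""

    times: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.times.shape != self.energy.shape:
            raise ValueError("times and energy must align")
        if np.any(self.energy < 0):
            raise ValueError("motion energy must be >= 0")


@dataclass
class MaskPair:
    """Embryo mask (trap window) and its shifted background copy (incubator
    window).  Both masks have identical pixel counts by construction."""

    embryo_mask: np.ndarray
    background_mask: np.ndarray
    shift: tuple[int, int]


@dataclass
class EventDetection:
    """Detected developmental events of one alive embryo.  ``hatched`` is
    False when no occupancy drop occurs within the stack; the duration is
    then undefined (NaN)."""

    t_twitch: float
    t_hatch: float
    hatched: bool

    @property
    def duration(self) -> float:
        return self.t_hatch - self.t_twitch if self.hatched else float("nan")


@dataclass
class EmbryoRecord:
    """Full per-embryo analysis output.

    ``trace_times``/``trace`` hold the hatch-aligned normalized intensity
    I_norm(t) with t = 0 at hatching and no post-hatch samples; for an
    unhatched embryo the trace is left unaligned and flagged.
    """

    site_index: int
    alive: bool
    t_twitch: float = float("nan")
    t_hatch: float = float("nan")
    duration: float = float("nan")
    hatched: bool = False
    trace_times: np.ndarray | None = None
    trace: np.ndarray | None = None


def build_masks(
    geometry: TrapGeometry,
    patch_size: int,
) -> MaskPair:
    """Construct the embryo/background mask pair for a patch size.

    The embryo mask is the egg footprint ellipse eroded by the geometry's
    mask margin, centred in the trap window; the background mask is the same
    shape translated by the configured shift into the incubator window (both
    windows are centred on their respective lumens, so in window coordinates
    the two masks coincide at the centre).
    """
    if geometry.mask_shift == 0:
        raise ValueError("mask_shift must be nonzero: embryo and background masks coincide")
    er = geometry.embryo_semi[0] - geometry.mask_margin
    ec = geometry.embryo_semi[1] - geometry.mask_margin
    if er <= 0 or ec <= 0:
        raise ValueError("mask margin leaves an empty embryo mask")
    half = patch_size // 2
    if er >= half or ec >= half:
        raise ValueError(
            f"embryo mask (semi-axes {er}×{ec}) does not fit a {patch_size} px patch"
        )
    rr = np.arange(patch_size)[:, None] - half
    cc = np.arange(patch_size)[None, :] - half
    mask = (rr / er) ** 2 + (cc / ec) ** 2 <= 1.0
    return MaskPair(
        embryo_mask=mask,
        background_mask=mask.copy(),
        shift=(-geometry.mask_shift, 0),
    )


def motion_trace(bf_trap: FrameStack, embryo_mask: np.ndarray) -> MotionTrace:
    """Motion energy over the embryo mask for every frame transition."""
    if bf_trap.n_frames < 2:
        raise ValueError("motion trace needs >= 2 frames")
    frames = bf_trap.frames[:, embryo_mask].astype(np.float32)
    energy = np.abs(np.diff(frames, axis=0)).mean(axis=1)
    return MotionTrace(times=bf_trap.times[1:], energy=energy)


def _noise_floor(trace: MotionTrace) -> float:
    return float(np.median(trace.energy[:NOISE_FLOOR_TRANSITIONS]))


def _sustained_exceedance(
    trace: MotionTrace, k: float, m: int
) -> int | None:
    """Index of the first transition opening a run of ``m`` consecutive
    exceedances of k× the noise floor, or None."""
    floor = _noise_floor(trace)
    thresh = k * floor if floor > 0 else 1e-9
    above = trace.energy > thresh
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= m:
            return i - m + 1
    return None


def classify_viability(
    trace: MotionTrace,
    k: float = MOTION_FACTOR,
    m: int = MOTION_RUN,
) -> bool:
    """Alive iff the motion energy shows a sustained exceedance of the noise
    floor (k×, ``m`` consecutive transitions)."""
    if len(trace.energy) < 3:
        raise ValueError("viability needs >= 3 transitions")
    return _sustained_exceedance(trace, k, m) is not None


def _occupancy(bf_trap: FrameStack, embryo_mask: np.ndarray) -> np.ndarray:
    """Per-frame fraction of embryo-mask pixels that are dark foreground.

    The dark/bright split is a single Otsu threshold over all mask pixels of
    the whole stack, which is bimodal as soon as the stack contains both
    embryo-present and trap-empty frames.
    """
    vals = bf_trap.frames[:, embryo_mask].astype(np.float32)
    thresh = threshold_otsu(vals.ravel())
    return (vals < thresh).mean(axis=1)


def detect_events(
    trace: MotionTrace,
    bf_trap: FrameStack,
    embryo_mask: np.ndarray,
    k: float = MOTION_FACTOR,
    m: int = MOTION_RUN,
) -> EventDetection:
    """Detect twitching onset and hatching for an embryo classified alive.

    Twitching is the first time of the sustained motion exceedance; hatching
    the first frame whose occupancy falls below 30 % of the running pre-hatch
    median (ties broken to the earlier frame).  If no such frame exists the
    record is flagged unhatched.
    """
    idx = _sustained_exceedance(trace, k, m)
    if idx is None:
        raise ValueError("no sustained motion: embryo is not classified alive")
    t_twitch = float(trace.times[idx])
    occ = _occupancy(bf_trap, embryo_mask)
    t_hatch = float("nan")
    hatched = False
    for f in range(3, len(occ)):
        median = float(np.median(occ[:f]))
        if occ[f] < HATCH_OCCUPANCY_FRACTION * median:
            t_hatch = float(bf_trap.times[f])
            hatched = True
            break
    return EventDetection(t_twitch=t_twitch, t_hatch=t_hatch, hatched=hatched)


def normalized_intensity(
    fl_trap: FrameStack,
    fl_incubator: FrameStack,
    masks: MaskPair,
) -> np.ndarray:
    """Per-frame normalized average embryo intensity.

    I_norm(t) = mean fluorescence over the embryo mask divided by the mean
    over the background mask; exactly invariant to a global gain applied to
    both channels' patches.
    """
    for stack, mask in ((fl_trap, masks.embryo_mask), (fl_incubator, masks.background_mask)):
        if stack.frame_shape != mask.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not fit patch {stack.frame_shape}"
            )
    embryo = fl_trap.frames[:, masks.embryo_mask].astype(np.float64).mean(axis=1)
    background = fl_incubator.frames[:, masks.background_mask].astype(np.float64).mean(axis=1)
    if np.any(background <= 0):
        raise ValueError("background mean fluorescence must be positive")
    return embryo / background


def hatch_aligned_trace(
    times: np.ndarray,
    i_norm: np.ndarray,
    t_hatch: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Align a per-frame I_norm series to the hatching event.

    Samples after ``t_hatch`` are removed and the remaining times are
    re-expressed as t − t_hatch, so the trace ends at t = 0 (the hatch).
    """
    times = np.asarray(times, dtype=float)
    i_norm = np.asarray(i_norm, dtype=float)
    keep = times <= t_hatch
    return times[keep] - t_hatch, i_norm[keep]


def analyze_trap_series(
    series: TrapPatchSeries,
    geometry: TrapGeometry | None = None,
    k: float = MOTION_FACTOR,
    m: int = MOTION_RUN,
) -> EmbryoRecord:
    """Run the full per-embryo pipeline on one trap patch series.

    Viability → (if alive) twitching/hatching detection → (if fluorescence
    present) background-normalized intensity, hatch-aligned.  Dead embryos
    never produce event times.
    """
    geometry = geometry or TrapGeometry()
    patch = series.bf_trap.frame_shape[0]
    masks = build_masks(geometry, patch)
    trace = motion_trace(series.bf_trap, masks.embryo_mask)
    if not classify_viability(trace, k, m):
        return EmbryoRecord(site_index=series.site_index, alive=False)
    events = detect_events(trace, series.bf_trap, masks.embryo_mask, k, m)
    record = EmbryoRecord(
        site_index=series.site_index,
        alive=True,
        t_twitch=events.t_twitch,
        t_hatch=events.t_hatch,
        duration=events.duration,
        hatched=events.hatched,
    )
    if series.fl_trap is not None and series.fl_incubator is not None:
        i_norm = normalized_intensity(series.fl_trap, series.fl_incubator, masks)
        if events.hatched:
            record.trace_times, record.trace = hatch_aligned_trace(
                series.fl_trap.times, i_norm, events.t_hatch
            )
        else:
            record.trace_times, record.trace = series.fl_trap.times.copy(), i_norm
    return record
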