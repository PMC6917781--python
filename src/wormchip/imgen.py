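"""Synthetic microscopy scenes with exact ground truth.

Every analysis stage of the package (chamber segmentation, trap localization,
embryo event detection, L1 morphometry, condition statistics) is validated
against renders from this module.  The generator emulates the device and the
biology's statistical structure:

* **Culture chambers** (brightfield, 30-min cadence, 3.2 µm/px at the 4×
  path): dark sinuous mother worms crawling over a textured chamber with
  constriction-filter pillars, growing along a logistic curve, laying
  ~50×30 µm eggs at scheduled times, under a linear illumination gradient and
  Gaussian read noise.
* **Serpentines**: a row of trap–incubator units (25 on the chip) rendered
  from a :class:`~wormchip.geometry.TrapGeometry`, with ground-truth
  intersection coordinates.
* **Trap patch series** (10-min cadence, 20× path): a confined embryo whose
  eggshell interior texture jitters after twitching onset and which vacates
  the trap at hatching; the paired fluorescence channel ramps the embryo's
  UPR^mt reporter intensity over a known background.
* **L1 larvae**: a sinusoidal tube of stated arc length and width with a
  fluorescent interior.

Ground truth is computed from the pre-noise scene, so it is exactly invariant
to ``noise_sd``; object masks are constructed so their pixel counts equal the
recorded truth areas exactly.  Identical :class:`SceneSpec` (including
``rng_seed``) yields bit-identical output.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import yaml
from scipy import ndimage, optimize

from . import _draw
from .geometry import TrapGeometry
from .io_core import BRIGHTFIELD, FLUORESCENCE, FrameStack

__all__ = [
    "SceneSpec",
    "LogisticGrowth",
    "WormSpec",
    "IntensityRamp",
    "EmbryoSpec",
    "GroundTruth",
    "ChamberSeries",
    "TrapPatchSeries",
    "render_chamber_series",
    "render_serpentine",
    "render_trap_series",
    "render_larva",
    "draw_embryo_spec",
    "DEVELOPMENT_TIME_INCREASE_PCT",
    "CONTROL_DURATION_MIN",
    "DURATION_SD_MIN",
    "TWITCH_WINDOW_MIN",
    "load_scene_spec",
    "save_scene_spec",
]

# 16-bit brightfield rendering levels (grayscale counts).
BF_BACKGROUND = 28000.0   # illuminated chamber / channel lumen
BF_WALL = 8000.0          # PDMS walls and pillars
BF_WORM = 9000.0          # worm body (dark on light)
BF_EGG = 16000.0
BF_EGGSHELL = 10000.0
BF_EMBRYO_INTERIOR = 15500.0
EMBRYO_TEXTURE_SD = 9000.0    # granular embryo interior; drives motion energy
EMBRYO_TEXTURE_CORR = 2.0     # px

# Fluorescence levels.  Read noise scales with the channel's dynamic range.
FL_BACKGROUND = 1200.0    # medium autofluorescence inside lumens
FL_WALL = 60.0
FL_NOISE_SCALE = FL_BACKGROUND / BF_BACKGROUND

WORM_ASPECT = 12.0        # body length / width for rendered adults
EGG_SEMI_UM = (25.0, 15.0)  # egg semi-axes, µm (50 × 30 µm ellipse)


@dataclass(frozen=True)
class SceneSpec:
    """Acquisition parameters of a synthetic scene.

    ``pixel_size`` defaults to the 20× imaging path (0.8 µm/px); use
    :meth:`for_chamber` for the 4× path (3.2 µm/px, 30-min cadence).
    ``illum_gradient`` is the fractional intensity change across the image
    width; ``noise_sd`` is Gaussian read noise in grayscale counts on the
    brightfield channel (the fluorescence channel is scaled by its dynamic
    range).
    """

    rng_seed: int = 0
    pixel_size: float = 0.8
    frame_interval: float = 10.0
    n_frames: int = 73
    noise_sd: float = 300.0
    illum_gradient: float = 0.1

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def for_chamber(cls, rng_seed: int = 0, n_frames: int = 49, **kw) -> "SceneSpec":
        kw.setdefault("pixel_size", 3.2)
        kw.setdefault("frame_interval", 30.0)
        return cls(rng_seed=rng_seed, n_frames=n_frames, **kw)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def load_scene_spec(path: str | os.PathLike) -> SceneSpec:
    with open(path) as fh:
        return SceneSpec(**(yaml.safe_load(fh) or {}))


def save_scene_spec(spec: SceneSpec, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


@dataclass(frozen=True)
class LogisticGrowth:
    """4-parameter logistic area curve: lower/upper asymptote (px²), rate
    (1/min) and midpoint time (min)."""

    lower: float
    upper: float
    rate: float
    midpoint: float

    def area(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.rate * (np.asarray(t, dtype=float) - self.midpoint))
        )


@dataclass
class WormSpec:
    """One mother worm: size trajectory, motion path and egg-laying schedule.

    ``growth`` of ``None`` keeps the worm at ``initial_area``.  A
    ``centroid_path`` of shape (n_frames, 2) pins per-frame positions;
    otherwise a smooth random walk inside the chamber is generated.
    ``egg_events`` are lay times in minutes, strictly increasing.
    """

    initial_area: float = 2000.0
    growth: LogisticGrowth | None = None
    centroid_path: np.ndarray | None = None
    egg_events: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        events = tuple(float(t) for t in self.egg_events)
        if any(b <= a for a, b in zip(events, events[1:])):
            raise ValueError("egg_events must be strictly increasing")
        self.egg_events = events
        if self.growth is not None:
            if not (0 < self.growth.lower <= self.growth.upper):
                raise ValueError("logistic asymptotes must satisfy 0 < lower <= upper")

    def area_at(self, t: np.ndarray) -> np.ndarray:
        if self.growth is None:
            return np.full(np.shape(t), float(self.initial_area))
        return np.asarray(self.growth.area(t), dtype=float)


@dataclass(frozen=True)
class IntensityRamp:
    """Piecewise-linear, non-decreasing normalized reporter intensity:
    ``value(t) = min(plateau, baseline + slope * t)`` in units of the
    fluorescence background mean."""

    baseline: float = 1.0
    slope: float = 0.0      # per minute
    plateau: float = 1.0

    def __post_init__(self) -> None:
        if self.slope < 0 or self.plateau < self.baseline:
            raise ValueError("intensity ramp must be non-decreasing")

    def value(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.minimum(self.plateau, self.baseline + self.slope * np.asarray(t, float))


@dataclass(frozen=True)
class EmbryoSpec:
    """One trapped embryo: viability, event times and reporter dynamics.

    Dead embryos are static (``twitch_amplitude`` forced semantics: must be
    0) and never hatch.  For alive embryos ``t_twitch < t_hatch``; a
    ``t_hatch`` beyond the imaging window simply never leaves the trap (the
    analysis flags such records "unhatched").
    """

    alive: bool = True
    t_twitch: float | None = None
    t_hatch: float | None = None
    intensity_ramp: IntensityRamp = field(default_factory=IntensityRamp)
    twitch_amplitude: float = 3.0   # px of intra-eggshell texture jitter

    def __post_init__(self) -> None:
        if self.alive:
            if self.t_twitch is None or self.t_hatch is None:
                raise ValueError("alive embryos need t_twitch and t_hatch")
            if not self.t_twitch < self.t_hatch:
                raise ValueError("alive embryos must satisfy t_twitch < t_hatch")
        else:
            if self.twitch_amplitude != 0:
                raise ValueError("dead embryos must have twitch_amplitude = 0")


@dataclass
class GroundTruth:
    """Exact render-time truth; only the fields relevant to a given renderer
    are populated.  All values are computed pre-noise."""

    times: np.ndarray | None = None
    # chamber
    total_area: np.ndarray | None = None        # px² per frame (union mask count)
    worm_areas: np.ndarray | None = None        # (n_frames, n_worms)
    egg_count: np.ndarray | None = None         # cumulative per frame
    collision: np.ndarray | None = None         # per-frame overlap flag
    masks: np.ndarray | None = None             # (n, h, w) union worm masks
    empty_frame: np.ndarray | None = None       # pre-noise worm-free render
    # serpentine
    trap_coords: np.ndarray | None = None       # (k, 2) intersections
    # trap series
    t_twitch: float | None = None
    t_hatch: float | None = None
    embryo_mean_intensity: np.ndarray | None = None   # pre-noise fluor mean
    background_mean_intensity: float | None = None
    normalized_intensity: np.ndarray | None = None
    embryo_mask: np.ndarray | None = None       # embryo footprint, trap-patch coords
    wall_mask: np.ndarray | None = None         # PDMS pixels, trap-patch coords
    # larva
    length_um: float | None = None
    diameter_um: float | None = None
    mean_intensity_norm: float | None = None
    max_intensity_norm: float | None = None
    larva_mask: np.ndarray | None = None
    spline_points: np.ndarray | None = None     # (k, 2) centreline control points
    area: int | None = None


@dataclass
class ChamberSeries:
    """Brightfield stack of one culture chamber plus its lane metadata."""

    stack: FrameStack
    n_worms: int
    condition: str = "CNT"
    dose: int = 0
    lane_id: str = "lane0"


@dataclass
class TrapPatchSeries:
    """Cropped per-frame patches of one trap–incubator unit (square,
    default 200 px).  Brightfield incubator patches exist but are unused by
    the analysis; fluorescence patches may be absent when only event
    detection is needed."""

    bf_trap: FrameStack
    bf_incubator: FrameStack | None = None
    fl_trap: FrameStack | None = None
    fl_incubator: FrameStack | None = None
    site_index: int = 0


def _rngs(spec: SceneSpec) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent scene and noise streams, so truth never depends on whether
    or how much noise is drawn."""
    scene_ss, noise_ss = np.random.SeedSequence(spec.rng_seed).spawn(2)
    return np.random.default_rng(scene_ss), np.random.default_rng(noise_ss)


# ---------------------------------------------------------------------------
# Culture chamber
# ---------------------------------------------------------------------------


def chamber_shape(spec: SceneSpec) -> tuple[int, int]:
    """Chamber footprint scaled from the 1540 µm × 2385 µm device feature."""
    return int(round(1540.0 / spec.pixel_size)), int(round(2385.0 / spec.pixel_size))


def _chamber_base(shape: tuple[int, int], spec: SceneSpec) -> np.ndarray:
    """Static pre-noise chamber: bright interior, wall border, 32 constriction
    filter pillars on each short side, linear illumination ramp."""
    h, w = shape
    img = np.full(shape, BF_BACKGROUND, dtype=np.float32)
    border = max(2, h // 120)
    wall = np.zeros(shape, dtype=bool)
    wall[:border, :] = wall[-border:, :] = True
    wall[:, :border] = wall[:, -border:] = True
    # filter pillars: short bars along both vertical edges
    n_filters = 32
    pillar_w = max(2, w // 150)
    slot = h / n_filters
    for i in range(n_filters):
        r0 = int(i * slot) + 1
        r1 = max(r0 + 1, int(i * slot + 0.55 * slot))
        wall[r0:r1, border : border + pillar_w] = True
        wall[r0:r1, w - border - pillar_w : w - border] = True
    alpha = _draw.soft_alpha(wall, 0.7)
    _draw.composite(img, alpha, BF_WALL)
    img *= _draw.illumination(shape, spec.illum_gradient)
    return img


def _worm_centerline(
    length: float,
    centroid: tuple[float, float],
    theta: float,
    phase: float,
    n_pts: int = 120,
) -> np.ndarray:
    """Sinuous body centreline of given arc-parameter length (px)."""
    s = np.linspace(-0.5, 0.5, n_pts) * length
    lateral = 0.12 * length * np.sin(2.0 * np.pi * 1.5 * s / length + phase)
    ct, st = np.cos(theta), np.sin(theta)
    rows = centroid[0] + st * s + ct * lateral
    cols = centroid[1] + ct * s - st * lateral
    return np.column_stack([rows, cols])


def render_chamber_series(
    spec: SceneSpec,
    worms: list[WormSpec],
    *,
    condition: str = "CNT",
    dose: int = 0,
    lane_id: str = "lane0",
    keep_masks: bool = True,
) -> tuple[ChamberSeries, GroundTruth]:
    """Render a brightfield culture-chamber time-lapse with ground truth.

    Truth records, per frame, the exact pixel count of the union worm mask
    (``total_area``), each worm's own mask count, the cumulative egg count,
    and a collision flag set when worm overlap exceeds 20 % of the union.
    """
    shape = chamber_shape(spec)
    h, w = shape
    rng, noise_rng = _rngs(spec)
    times = spec.times
    n = spec.n_frames

    base = _chamber_base(shape, spec)
    margin = int(0.12 * min(h, w))

    # per-worm motion state
    paths = []
    thetas = []
    phases = []
    for worm in worms:
        if worm.centroid_path is not None:
            path = np.asarray(worm.centroid_path, dtype=float)
            if path.shape != (n, 2):
                raise ValueError(
                    f"centroid_path must have shape ({n}, 2), got {path.shape}"
                )
            if (
                path[:, 0].min() < 0
                or path[:, 1].min() < 0
                or path[:, 0].max() >= h
                or path[:, 1].max() >= w
            ):
                raise ValueError("worm centroids must lie within the chamber footprint")
        else:
            start = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            steps = rng.normal(0.0, 9.0, size=(n, 2))
            steps[0] = 0.0
            path = np.cumsum(steps, axis=0) + start
            path[:, 0] = np.clip(path[:, 0], margin, h - margin)
            path[:, 1] = np.clip(path[:, 1], margin, w - margin)
        paths.append(path)
        thetas.append(rng.uniform(0, 2 * np.pi))
        phases.append(rng.uniform(0, 2 * np.pi))

    # egg positions fixed at lay time
    egg_semi = (EGG_SEMI_UM[1] / spec.pixel_size, EGG_SEMI_UM[0] / spec.pixel_size)
    all_events = sorted(t for worm in worms for t in worm.egg_events)
    egg_pos = [
        (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        for _ in all_events
    ]

    frames = np.empty((n, h, w), dtype=np.float32)
    total_area = np.zeros(n, dtype=np.int64)
    worm_areas = np.zeros((n, len(worms)), dtype=np.int64)
    collision = np.zeros(n, dtype=bool)
    egg_count = np.zeros(n, dtype=np.int64)
    masks = np.zeros((n, h, w), dtype=bool) if keep_masks else None

    for f, t in enumerate(times):
        img = base.copy()
        union = np.zeros(shape, dtype=bool)
        indiv_sum = 0
        for k, worm in enumerate(worms):
            area = int(round(float(worm.area_at(np.array([t]))[0])))
            if area <= 0:
                continue
            length = np.sqrt(WORM_ASPECT * area)
            halfwidth = area / length / 2.0
            pts = _worm_centerline(
                length, tuple(paths[k][f]), thetas[k], phases[k] + 0.9 * f
            )
            pts[:, 0] = np.clip(pts[:, 0], 2, h - 3)
            pts[:, 1] = np.clip(pts[:, 1], 2, w - 3)
            mask = _draw.tube_mask_exact_area(shape, pts, area, halfwidth)
            worm_areas[f, k] = int(mask.sum())
            indiv_sum += worm_areas[f, k]
            union |= mask
        total_area[f] = int(union.sum())
        if total_area[f] > 0 and indiv_sum - total_area[f] > 0.2 * total_area[f]:
            collision[f] = True
        if masks is not None:
            masks[f] = union
        alpha = _draw.soft_alpha(union, 0.8)
        _draw.composite(img, alpha, BF_WORM)
        laid = [i for i, ev in enumerate(all_events) if ev <= t]
        egg_count[f] = len(laid)
        if laid:
            egg_union = np.zeros(shape, dtype=bool)
            for i in laid:
                egg_union |= _draw.ellipse_mask(shape, egg_pos[i], egg_semi)
            _draw.composite(img, _draw.soft_alpha(egg_union, 0.6), BF_EGG)
        frames[f] = img

    out = _draw.finalize_u16(frames, spec.noise_sd, noise_rng)
    stack = FrameStack(out, times, BRIGHTFIELD, spec.pixel_size)
    truth = GroundTruth(
        times=times,
        total_area=total_area,
        worm_areas=worm_areas,
        egg_count=egg_count,
        collision=collision,
        masks=masks,
        empty_frame=base,
    )
    series = ChamberSeries(
        stack=stack, n_worms=len(worms), condition=condition, dose=dose, lane_id=lane_id
    )
    return series, truth


# ---------------------------------------------------------------------------
# Serpentine and trap units
# ---------------------------------------------------------------------------


def _unit_lumen(
    shape: tuple[int, int],
    intersection: tuple[int, int],
    geom: TrapGeometry,
) -> np.ndarray:
    """Lumen (flow volume) mask of one trap–incubator unit."""
    ir, ic = geom.incubator_center(intersection)
    tr, tc = geom.trap_center(intersection)
    lumen = _draw.ellipse_mask(shape, (ir, ic), geom.incubator_semi)
    lumen |= _draw.ellipse_mask(shape, (tr, tc), geom.trap_semi)
    lumen |= _draw.rect_mask(
        shape, ir, tr, ic - geom.neck_halfwidth, ic + geom.neck_halfwidth
    )
    # wing-shaped tips flanking the trap exit
    wing_c = geom.trap_semi[1] - 2 * geom.wing_halfwidth
    for side in (-1, 1):
        lumen |= _draw.rect_mask(
            shape,
            tr + geom.trap_semi[0] - 2,
            tr + geom.trap_semi[0] + geom.wing_len,
            tc + side * wing_c - geom.wing_halfwidth,
            tc + side * wing_c + geom.wing_halfwidth,
        )
    return lumen


def _serpentine_scene(
    shape: tuple[int, int],
    intersections: list[tuple[int, int]],
    geom: TrapGeometry,
    gradient: float,
    channel_band: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-noise brightfield serpentine and its lumen mask."""
    lumen = np.zeros(shape, dtype=bool)
    if channel_band and intersections:
        row = geom.incubator_center(intersections[0])[0]
        lumen |= _draw.rect_mask(
            shape, row - geom.channel_halfheight, row + geom.channel_halfheight, 0, shape[1]
        )
    for inter in intersections:
        lumen |= _unit_lumen(shape, inter, geom)
    img = np.full(shape, BF_WALL, dtype=np.float32)
    _draw.composite(img, _draw.soft_alpha(lumen, 1.0), BF_BACKGROUND)
    img *= _draw.illumination(shape, gradient)
    return img, lumen


def render_serpentine(
    spec: SceneSpec,
    geometry: TrapGeometry | None = None,
    n_traps: int | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render a single brightfield serpentine image with trap-unit truth.

    Truth coordinates are the trap–incubator intersection points, ordered
    along the serpentine; they are independent of ``noise_sd`` and of the
    seed (unit placement is deterministic given the geometry).
    """
    geom = geometry or TrapGeometry()
    n = geom.n_units if n_traps is None else int(n_traps)
    if n < 1:
        raise ValueError("n_traps must be >= 1")
    shape = geom.serpentine_shape(n)
    inters = geom.intersections(n)
    _, noise_rng = _rngs(spec)
    img, _lumen = _serpentine_scene(shape, inters, geom, spec.illum_gradient)
    out = _draw.finalize_u16(img[None], spec.noise_sd, noise_rng)
    stack = FrameStack(out, np.array([0.0]), BRIGHTFIELD, spec.pixel_size)
    truth = GroundTruth(trap_coords=np.array(inters, dtype=int))
    return stack, truth


@lru_cache(maxsize=8)
def _trap_scene_cached(
    geom: TrapGeometry, patch: int, gradient: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int], tuple[int, int]]:
    """Static pre-noise scene around one unit, sized to contain both the
    trap-centred and incubator-centred windows of size ``patch``.

    Returns (bf_scene, fl_scene, lumen, trap_origin, incubator_origin) where
    the origins are the top-left corners of the two windows.
    """
    scene_shape = (patch + geom.mask_shift, patch)
    inter = (patch // 2 + geom.mask_shift // 2, patch // 2)
    bf, lumen = _serpentine_scene(scene_shape, [inter], geom, gradient)
    fl = np.full(scene_shape, FL_WALL, dtype=np.float32)
    _draw.composite(fl, _draw.soft_alpha(lumen, 1.0), FL_BACKGROUND)
    fl *= _draw.illumination(scene_shape, gradient)
    tr, tc = geom.trap_center(inter)
    ir, ic = geom.incubator_center(inter)
    trap_origin = (tr - patch // 2, tc - patch // 2)
    inc_origin = (ir - patch // 2, ic - patch // 2)
    return bf, fl, lumen, trap_origin, inc_origin


def render_trap_series(
    spec: SceneSpec,
    embryo: EmbryoSpec,
    geometry: TrapGeometry | None = None,
    patch_size: int = 200,
    channels: tuple[str, ...] = (BRIGHTFIELD, FLUORESCENCE),
    site_index: int = 0,
) -> tuple[TrapPatchSeries, GroundTruth]:
    """Render paired brightfield/fluorescence patch stacks of one embryo trap.

    Brightfield: the eggshell ellipse with granular interior texture sits
    centred in the trap; after ``t_twitch`` the texture jitters by up to
    ``twitch_amplitude`` px per frame, and from ``t_hatch`` on the trap is
    empty.  Fluorescence: the embryo interior follows ``intensity_ramp``
    (units of the background mean); truth records the pre-noise per-frame
    mean embryo intensity and its background-normalized ratio.
    """
    geom = geometry or TrapGeometry()
    patch = int(patch_size)
    if patch < 2 * (geom.incubator_semi[1] + 4):
        raise ValueError(f"patch_size {patch} too small for the trap geometry")
    rng, noise_rng = _rngs(spec)
    times = spec.times
    n = spec.n_frames
    want_bf = BRIGHTFIELD in channels
    want_fl = FLUORESCENCE in channels
    if not (want_bf or want_fl):
        raise ValueError("at least one channel must be rendered")

    bf_scene, fl_scene, lumen, trap_origin, inc_origin = _trap_scene_cached(
        geom, patch, spec.illum_gradient
    )

    # embryo footprint, centred in the trap; scene coordinates
    center = (trap_origin[0] + patch // 2, trap_origin[1] + patch // 2)
    er, ec = geom.embryo_semi
    scene_shape = bf_scene.shape
    shell = _draw.ellipse_mask(scene_shape, center, (er, ec))
    interior = _draw.ellipse_mask(scene_shape, center, (er - 2, ec - 2))
    shell_alpha = _draw.soft_alpha(shell, 0.8)
    interior_alpha = _draw.soft_alpha(interior, 0.8)

    jit = max(1, int(np.ceil(embryo.twitch_amplitude)))
    r0, r1 = center[0] - er - 2, center[0] + er + 3
    c0, c1 = center[1] - ec - 2, center[1] + ec + 3
    texture = _draw.smooth_field(
        (r1 - r0 + 2 * jit, c1 - c0 + 2 * jit), rng, EMBRYO_TEXTURE_CORR, EMBRYO_TEXTURE_SD
    )

    # per-frame texture offsets: zero before twitching, absent after hatching;
    # while twitching, every frame-to-frame displacement is nonzero
    offsets = np.zeros((n, 2), dtype=int)
    present = np.ones(n, dtype=bool)
    if embryo.alive:
        moving = (times >= embryo.t_twitch) & (times < embryo.t_hatch)
        present = times < embryo.t_hatch
        amp = int(round(embryo.twitch_amplitude))
        if amp > 0:
            prev = (0, 0)
            for f in np.flatnonzero(moving):
                while True:
                    cand = (
                        int(rng.integers(-amp, amp + 1)),
                        int(rng.integers(-amp, amp + 1)),
                    )
                    if cand != (0, 0) and cand != prev:
                        break
                offsets[f] = cand
                prev = cand

    bf_stack = np.repeat(bf_scene[None], n, axis=0) if want_bf else None
    fl_stack = np.repeat(fl_scene[None], n, axis=0) if want_fl else None
    embryo_mean = np.full(n, np.nan)

    sh_a = shell_alpha[r0:r1, c0:c1]
    in_a = interior_alpha[r0:r1, c0:c1]
    ramp_values = np.asarray(embryo.intensity_ramp.value(times), dtype=float)
    for f in range(n):
        if not present[f]:
            continue
        dr, dc = offsets[f]
        if want_bf:
            tex = texture[
                jit + dr : jit + dr + (r1 - r0), jit + dc : jit + dc + (c1 - c0)
            ]
            box = bf_stack[f, r0:r1, c0:c1]
            box *= 1.0 - sh_a
            box += sh_a * BF_EGGSHELL
            vals = np.clip(BF_EMBRYO_INTERIOR + tex, 0, _draw.U16_MAX)
            box *= 1.0 - in_a
            box += in_a * vals
        if want_fl:
            box = fl_stack[f, r0:r1, c0:c1]
            level = float(ramp_values[f]) * FL_BACKGROUND
            box *= 1.0 - sh_a
            box += sh_a * level
            embryo_mean[f] = float(fl_stack[f][shell].mean())
        else:
            # pre-noise truth is defined even when the channel is not rendered
            embryo_mean[f] = float(ramp_values[f]) * FL_BACKGROUND

    # embryo footprint shifted into the incubator lumen = background reference
    bg_mask = np.roll(shell, -geom.mask_shift, axis=0)
    bg_mean = float(fl_scene[bg_mask].mean())

    def crop(arr: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
        r, c = origin
        return arr[..., r : r + patch, c : c + patch].copy()

    bf_trap = bf_inc = fl_trap = fl_inc = None
    if want_bf:
        bf_out = _draw.finalize_u16(bf_stack, spec.noise_sd, noise_rng)
        bf_trap = FrameStack(crop(bf_out, trap_origin), times, BRIGHTFIELD, spec.pixel_size)
        bf_inc = FrameStack(crop(bf_out, inc_origin), times, BRIGHTFIELD, spec.pixel_size)
    if want_fl:
        fl_out = _draw.finalize_u16(fl_stack, spec.noise_sd * FL_NOISE_SCALE, noise_rng)
        fl_trap = FrameStack(crop(fl_out, trap_origin), times, FLUORESCENCE, spec.pixel_size)
        fl_inc = FrameStack(crop(fl_out, inc_origin), times, FLUORESCENCE, spec.pixel_size)

    series = TrapPatchSeries(
        bf_trap=bf_trap,
        bf_incubator=bf_inc,
        fl_trap=fl_trap,
        fl_incubator=fl_inc,
        site_index=site_index,
    )
    truth = GroundTruth(
        times=times,
        t_twitch=embryo.t_twitch if embryo.alive else None,
        t_hatch=embryo.t_hatch if embryo.alive else None,
        embryo_mean_intensity=embryo_mean,
        background_mean_intensity=bg_mean,
        normalized_intensity=embryo_mean / bg_mean,
        embryo_mask=crop(shell, trap_origin),
        wall_mask=crop(~lumen, trap_origin),
    )
    return series, truth


# ---------------------------------------------------------------------------
# L1 larva
# ---------------------------------------------------------------------------


def render_larva(
    spec: SceneSpec,
    length_um: float,
    diameter_um: float,
    gfp_level: float,
    curvature: float = 0.12,
    n_control_points: int = 8,
) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Render a brightfield/fluorescence image pair of one L1 larva.

    The larva is a round-capped sinusoidal tube whose tip-to-tip centreline
    length is ``length_um`` and width ``diameter_um``; ``curvature`` is the
    undulation amplitude as a fraction of body length (0 → straight).
    ``gfp_level`` is the interior fluorescence in units of the background
    mean.  Truth records length, diameter, the pre-noise mean/max interior
    intensity (background-normalized) and centreline control points usable as
    an operator spline annotation.
    """
    if not length_um > diameter_um > 0:
        raise ValueError("require length_um > diameter_um > 0")
    px = spec.pixel_size
    length = length_um / px
    width = diameter_um / px
    halfwidth = width / 2.0
    chord = length - width  # straight-cap-compensated centreline span
    if chord <= 0:
        raise ValueError("length too small for the requested diameter")
    rng, noise_rng = _rngs(spec)

    amp = curvature * chord
    n_waves = 1.25

    def arc_length(span: float) -> float:
        t = np.linspace(0.0, 1.0, 2001)
        dr = amp * 2 * np.pi * n_waves * np.cos(2 * np.pi * n_waves * t)
        return float(np.trapezoid(np.hypot(span, dr), t))

    if amp == 0:
        span = chord
    else:
        span = optimize.brentq(lambda s: arc_length(s) - chord, chord * 0.2, chord)

    shape = (
        int(np.ceil(2 * amp + width + 40)),
        int(np.ceil(span + width + 40)),
    )
    t = np.linspace(0.0, 1.0, 600)
    rows = shape[0] / 2.0 + amp * np.sin(2 * np.pi * n_waves * t)
    cols = (shape[1] - span) / 2.0 + span * t
    pts = np.column_stack([rows, cols])
    mask = _draw.tube_mask(shape, pts, halfwidth)

    # control points along the full tip-to-tip centreline (caps included)
    def tangent(i0: int, i1: int) -> np.ndarray:
        d = pts[i1] - pts[i0]
        return d / np.linalg.norm(d)

    tip0 = pts[0] - tangent(0, 5) * halfwidth
    tip1 = pts[-1] + tangent(-6, -1) * halfwidth
    idx = np.linspace(0, len(pts) - 1, n_control_points - 2).astype(int)
    control = np.vstack([tip0, pts[idx[1:-1]], tip1])

    alpha = _draw.soft_alpha(mask, 0.8)
    bf = np.full(shape, BF_BACKGROUND, dtype=np.float32)
    bf *= _draw.illumination(shape, spec.illum_gradient)
    _draw.composite(bf, alpha, BF_WORM)

    fl = np.full(shape, FL_BACKGROUND, dtype=np.float32)
    level = gfp_level * FL_BACKGROUND
    interior_tex = _draw.smooth_field(shape, rng, 2.0, 0.05 * level)
    _draw.composite(fl, alpha, level)
    fl[mask] += interior_tex[mask]
    np.clip(fl, 0.0, _draw.U16_MAX, out=fl)

    mean_norm = float(fl[mask].mean()) / FL_BACKGROUND
    max_norm = float(fl[mask].max()) / FL_BACKGROUND

    bf_u = _draw.finalize_u16(bf[None], spec.noise_sd, noise_rng)
    fl_u = _draw.finalize_u16(fl[None], spec.noise_sd * FL_NOISE_SCALE, noise_rng)
    bf_stack = FrameStack(bf_u, np.array([0.0]), BRIGHTFIELD, px)
    fl_stack = FrameStack(fl_u, np.array([0.0]), FLUORESCENCE, px)
    truth = GroundTruth(
        length_um=float(length_um),
        diameter_um=float(diameter_um),
        mean_intensity_norm=mean_norm,
        max_intensity_norm=max_norm,
        larva_mask=mask,
        spline_points=control,
        area=int(mask.sum()),
    )
    return bf_stack, fl_stack, truth


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------

#: Percent increase in mean twitching-to-hatching duration versus control for
#: each (condition, dose µg/mL) treatment arm on the platform.  Mother-treated
#: arms (OMT 15 h exposure, MET continuous) lag dose-dependently; embryo-only
#: treatment does not (eggshell impermeability), and continuous treatment at
#: 60 µg/mL suppresses egg laying entirely, so that arm has no embryos.
DEVELOPMENT_TIME_INCREASE_PCT: dict[tuple[str, int], float] = {
    ("CNT", 0): 0.0,
    ("CNT", 15): 0.0,
    ("CNT", 30): 0.0,
    ("CNT", 60): 0.0,
    ("OET", 15): 0.0,
    ("OET", 30): 0.0,
    ("OET", 60): 0.0,
    ("OMT", 15): 4.0,
    ("OMT", 30): 7.0,
    ("OMT", 60): 5.0,
    ("MET", 15): 6.0,
    ("MET", 30): 9.0,
}

#: Control twitching-to-hatching duration, minutes.
CONTROL_DURATION_MIN = 420.0

#: Between-embryo duration spread, minutes.  Deliberately small relative to
#: the 10-min imaging cadence so arm-level contrasts are identifiable at
#: n = 30/arm; see docs/methods.md.
DURATION_SD_MIN = 2.0

#: Twitching onset window after trapping, minutes.
TWITCH_WINDOW_MIN = (180.0, 300.0)


def draw_embryo_spec(
    rng: np.random.Generator,
    condition: str = "CNT",
    dose: int = 0,
    alive: bool = True,
    twitch_amplitude: float = 3.0,
) -> EmbryoSpec:
    """Draw one embryo from a (condition, dose) treatment preset.

    Duration ~ Normal(420 × (1 + pct/100), 2) min with twitch onset uniform
    in [180, 300] min.  UPR^mt induction (ramp plateau 1.6× background) is
    applied for mother-treated arms at ≥30 µg/mL, mirroring the platform's
    dose threshold; other arms drift mildly to 1.1×.
    """
    if not alive:
        return EmbryoSpec(alive=False, twitch_amplitude=0.0)
    key = (condition, int(dose))
    if key == ("MET", 60):
        raise ValueError(
            "no embryos under continuous treatment at 60 µg/mL: egg laying is suppressed"
        )
    if key not in DEVELOPMENT_TIME_INCREASE_PCT:
        raise ValueError(f"unknown treatment preset {key!r}")
    pct = DEVELOPMENT_TIME_INCREASE_PCT[key]
    t_twitch = float(rng.uniform(*TWITCH_WINDOW_MIN))
    duration = float(rng.normal(CONTROL_DURATION_MIN * (1.0 + pct / 100.0), DURATION_SD_MIN))
    return _embryo_from_times(condition, dose, t_twitch, duration, twitch_amplitude)


def _embryo_from_times(
    condition: str,
    dose: int,
    t_twitch: float,
    duration: float,
    twitch_amplitude: float,
) -> EmbryoSpec:
    induced = condition in ("OMT", "MET") and dose >= 30
    plateau = 1.6 if induced else 1.1
    ramp = IntensityRamp(baseline=1.0, slope=(plateau - 1.0) / 600.0, plateau=plateau)
    return EmbryoSpec(
        alive=True,
        t_twitch=t_twitch,
        t_hatch=t_twitch + duration,
        intensity_ramp=ramp,
        twitch_amplitude=twitch_amplitude,
    )


def draw_embryo_arm(
    rng: np.random.Generator,
    condition: str,
    dose: int,
    n: int,
    twitch_amplitude: float = 3.0,
) -> list[EmbryoSpec]:
    """Draw one treatment arm of ``n`` embryos with stratified sampling.

    Arm-level contrasts are estimated from small samples (n = 30 per arm on
    the platform), where two Monte Carlo noise sources dominate: the sample
    mean of the duration draws, and aliasing of event times against the
    10-min acquisition grid.  Both are suppressed by standard stratification
    without changing the marginal distributions: twitch onsets are drawn
    with a Latin-hypercube-stratified phase relative to the frame interval
    (so an arm samples acquisition phase uniformly), and durations use
    quantile-stratified normal draws.  See docs/methods.md.
    """
    from scipy.stats import norm as _norm

    key = (condition, int(dose))
    if key == ("MET", 60):
        raise ValueError(
            "no embryos under continuous treatment at 60 µg/mL: egg laying is suppressed"
        )
    if key not in DEVELOPMENT_TIME_INCREASE_PCT:
        raise ValueError(f"unknown treatment preset {key!r}")
    mu = CONTROL_DURATION_MIN * (1.0 + DEVELOPMENT_TIME_INCREASE_PCT[key] / 100.0)
    interval = 10.0
    lo, hi = TWITCH_WINDOW_MIN
    n_slots = int((hi - lo) / interval)
    base = lo + interval * rng.integers(0, n_slots, n)
    phase = (rng.permutation(n) + rng.uniform(0, 1, n)) * (interval / n)
    quantile = (rng.permutation(n) + rng.uniform(0, 1, n)) / n
    durations = mu + DURATION_SD_MIN * _norm.ppf(quantile)
    return [
        _embryo_from_times(condition, dose, float(t), float(d), twitch_amplitude)
        for t, d in zip(base + phase, durations)
    ]
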