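"""L1 progeny morphometry and background-normalized fluorescence.

Length is the arc length of a cubic spline traced through the larva — either
an operator's control points (the platform's annotation mode) or the pruned
skeleton of a segmented mask with endpoints extended to the mask boundary
(automated mode).  The diameter is the mask chord perpendicular to the spline
at a configurable arc-length fraction (default mid-body, standing in for the
vulva position, which is not visually resolvable at L1).  Fluorescence is
quantified as the mean and maximum intensity inside the worm outline divided
by the average intensity of random background circles drawn in worm-free
areas (seeded, reproducible placement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from shapely.geometry import LineString
from skimage.morphology import disk, skeletonize

__all__ = [
    "LarvaMeasurement",
    "fit_spline",
    "measure_length",
    "measure_diameter",
    "larva_intensity",
    "mask_to_spline_points",
]

BACKGROUND_CIRCLES = 5
CIRCLE_RADIUS_PX = 15
CIRCLE_CLEARANCE_PX = 10
MAX_CIRCLE_DRAWS = 100


@dataclass
class LarvaMeasurement:
    """Morphometry and normalized fluorescence of one L1 larva."""

    length_um: float
    diameter_um: float
    mean_intensity_norm: float
    max_intensity_norm: float

    def __post_init__(self) -> None:
        if not self.length_um > self.diameter_um > 0:
            raise ValueError("require length > diameter > 0")
        if not (self.mean_intensity_norm > 0 and self.max_intensity_norm > 0):
            raise ValueError("normalized intensities must be positive")


def fit_spline(points: np.ndarray, smoothing: float = 0.0):
    """Cubic parametric spline through ordered (row, col) control points.

    Raises for fewer than 4 points or a self-intersecting path.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 2:
        raise ValueError(f"need >= 4 (row, col) control points, got shape {pts.shape}")
    dense_check = LineString(pts[:, ::-1])
    if not dense_check.is_simple:
        raise ValueError("spline control polygon is self-intersecting")
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=smoothing, k=3)
    return tck


def _spline_samples(tck, n: int = 2000) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    rows, cols = interpolate.splev(u, tck)
    return np.column_stack([rows, cols])


def _arc_length_px(tck, n: int = 2000) -> float:
    pts = _spline_samples(tck, n)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def mask_to_spline_points(mask: np.ndarray, n_points: int = 12) -> np.ndarray:
    """Centreline control points from a single-component worm mask.

    The mask is skeletonized, the skeleton pruned to its longest path (two
    breadth-first passes), and the path's endpoints extended outward to the
    mask boundary along the end tangents.
    """
    mask = np.asarray(mask, dtype=bool)
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one component, found {n_comp}")
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) < 4:
        raise ValueError("skeleton too short to trace")
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    neighbors: list[list[int]] = [[] for _ in coords]
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for (r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)

    def farthest(start: int) -> tuple[int, list[int]]:
        prev = {start: -1}
        queue = [start]
        last = start
        while queue:
            nxt = []
            for node in queue:
                for nb in neighbors[node]:
                    if nb not in prev:
                        prev[nb] = node
                        nxt.append(nb)
            if nxt:
                last = nxt[-1]
            queue = nxt
        path = [last]
        while prev[path[-1]] != -1:
            path.append(prev[path[-1]])
        return last, path[::-1]

    end_a, _ = farthest(0)
    _, path = farthest(end_a)
    path_pts = coords[path].astype(float)

    def extend(tip: np.ndarray, inward: np.ndarray) -> np.ndarray:
        direction = tip - inward
        norm = np.linalg.norm(direction)
        if norm == 0:
            return tip
        direction /= norm
        pos = tip.copy()
        h, w = mask.shape
        while True:
            nxt = pos + direction
            r, c = int(round(nxt[0])), int(round(nxt[1]))
            if r < 0 or c < 0 or r >= h or c >= w or not mask[r, c]:
                return pos
            pos = nxt

    k = min(6, len(path_pts) - 1)
    head = extend(path_pts[0], path_pts[k])
    tail = extend(path_pts[-1], path_pts[-1 - k])
    idx = np.linspace(0, len(path_pts) - 1, max(4, n_points - 2)).astype(int)
    return np.vstack([head, path_pts[idx[1:-1]], tail])


def measure_length(
    points_or_mask: np.ndarray,
    pixel_size: float,
) -> float:
    """Arc length of the larva centreline spline, in µm.

    Accepts either ordered control points (operator annotation, ≥ 4 points)
    or a boolean single-component mask (automated skeleton mode).
    """
    arr = np.asarray(points_or_mask)
    if arr.dtype == bool or arr.ndim == 2 and arr.shape[1] > 2:
        points = mask_to_spline_points(arr.astype(bool))
    else:
        points = arr
    tck = fit_spline(points)
    return _arc_length_px(tck) * pixel_size


def measure_diameter(
    points: np.ndarray,
    mask: np.ndarray,
    pixel_size: float,
    position_fraction: float = 0.5,
) -> float:
    """Mask chord perpendicular to the spline at an arc-length fraction, µm.

    The default mid-body fraction stands in for the vulva position.  Raises
    when the normal line misses the mask entirely (degenerate mask).
    """
    if not 0.0 < position_fraction < 1.0:
        raise ValueError("position_fraction must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    tck = fit_spline(np.asarray(points, dtype=float))
    samples = _spline_samples(tck)
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = position_fraction * cum[-1]
    i = int(np.searchsorted(cum, target))
    i = min(max(i, 1), len(samples) - 2)
    point = samples[i]
    tangent = samples[i + 1] - samples[i - 1]
    tangent /= np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])

    h, w = mask.shape
    step = 0.25

    def march(direction: np.ndarray) -> float:
        dist = 0.0
        while True:
            nxt = point + direction * (dist + step)
            r, c = int(round(nxt[0])), int(round(nxt[1]))
            if r < 0 or c < 0 or r >= h or c >= w or not mask[r, c]:
                return dist
            dist += step

    r0, c0 = int(round(point[0])), int(round(point[1]))
    if r0 < 0 or c0 < 0 or r0 >= h or c0 >= w or not mask[r0, c0]:
        raise ValueError("spline normal misses the mask at the requested position")
    chord = march(normal) + march(-normal) + step  # centre pixel contributes one step
    if chord <= step:
        raise ValueError("degenerate zero-width mask")
    return chord * pixel_size


def larva_intensity(
    fl_image: np.ndarray,
    outline_mask: np.ndarray,
    rng_seed: int = 0,
    n_circles: int = BACKGROUND_CIRCLES,
    circle_radius: int = CIRCLE_RADIUS_PX,
) -> tuple[float, float]:
    """Background-normalized mean and maximum intensity of a larva.

    The background is the average pixel intensity over ``n_circles`` random
    circles (radius 15 px) rejection-sampled outside a 10-px dilation of the
    worm; placement is seeded and reproducible.  Circles intersecting the
    worm (or the image border) are redrawn; after 100 failed draws an error
    is raised.  Both ratios are exactly invariant to a global gain.
    """
    img = np.asarray(fl_image, dtype=np.float64)
    mask = np.asarray(outline_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and outline mask shapes differ")
    if n_circles < 3:
        raise ValueError("need >= 3 background circles")
    forbidden = ndimage.binary_dilation(mask, disk(CIRCLE_CLEARANCE_PX))
    h, w = img.shape
    rng = np.random.default_rng(rng_seed)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    circle_values = []
    draws = 0
    while len(circle_values) < n_circles:
        if draws >= MAX_CIRCLE_DRAWS:
            raise ValueError(
                f"could not place {n_circles} worm-free circles in {MAX_CIRCLE_DRAWS} draws"
            )
        draws += 1
        r = rng.uniform(circle_radius, h - circle_radius)
        c = rng.uniform(circle_radius, w - circle_radius)
        circle = (rr - r) ** 2 + (cc - c) ** 2 <= circle_radius**2
        if (circle & forbidden).any():
            continue
        circle_values.append(img[circle])
    background = float(np.concatenate(circle_values).mean())
    if background <= 0:
        raise ValueError("background intensity must be positive")
    inside = img[mask]
    return float(inside.mean()) / background, float(inside.max()) / background
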