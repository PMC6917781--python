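"""Mother-worm segmentation and growth/egg phenotypes in culture chambers.

The brightfield time-lapse of a chamber (30-min cadence) is processed as:
background subtraction against a pixel-wise temporal median, Otsu
binarization of the absolute difference image, morphological opening and
closing, and small-fragment removal — leaving only background-isolated
nematodes.  The non-zero pixel count of the mask is the total worm area; the
normalized area divides by the number of worms cultured in the chamber.
Development is summarized by a 4-parameter logistic fit, and egg-release
phenotypes are derived from cumulative per-frame egg counts (operator
annotations or generator truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io_core import FrameStack

__all__ = [
    "SegmentationConfig",
    "GrowthTrace",
    "GrowthFit",
    "EggPhenotypes",
    "estimate_background",
    "segment_worms",
    "growth_trace",
    "fit_growth_sigmoid",
    "egg_phenotypes",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Pinned defaults for the morphological cleanup.

    ``opening_radius``/``closing_radius`` are disk radii in px; fragments
    below ``min_fragment_px`` (px²) are discarded, which also drops rendered
    eggs smaller than the cutoff.
    """

    opening_radius: int = 1
    closing_radius: int = 2
    min_fragment_px: int = 50


@dataclass
class GrowthTrace:
    """Per-frame total and per-worm segmented area of one chamber."""

    times: np.ndarray
    total_area: np.ndarray
    n_worms: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_area = np.asarray(self.total_area, dtype=float)
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if np.any(self.total_area < 0):
            raise ValueError("areas must be >= 0")

    @property
    def normalized_area(self) -> np.ndarray:
        return self.total_area / self.n_worms


@dataclass
class GrowthFit:
    """4-parameter logistic fit of a growth trace.

    ``converged`` is False when least squares failed; ``degenerate`` is True
    for flat traces where the rate/midpoint are unidentifiable.  ``fitted``
    evaluates the model on the trace's own time grid.
    """

    lower: float
    upper: float
    rate: float
    midpoint: float
    rmse: float
    converged: bool
    degenerate: bool
    fitted: np.ndarray


def _logistic(t, lower, upper, rate, midpoint):
    return lower + (upper - lower) / (1.0 + np.exp(-rate * (t - midpoint)))


def estimate_background(stack: FrameStack) -> np.ndarray:
    """Pixel-wise temporal median — the static chamber structure.

    Worms that keep moving are suppressed; walls, pillars and the
    illumination profile are retained.  Requires at least 3 frames for the
    median to reject a transient foreground.
    """
    if stack.n_frames < 3:
        raise ValueError(
            f"background estimation needs >= 3 frames, got {stack.n_frames}"
        )
    return np.median(stack.frames, axis=0).astype(np.float32)


def segment_worms(
    frame: np.ndarray,
    background: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Binary worm mask of one frame against a static background.

    |frame − background| is thresholded by Otsu, opened (disk r=1), closed
    (disk r=2) and cleared of fragments below the configured minimum.  A
    frame indistinguishable from the background yields an empty mask.
    """
    frame = np.asarray(frame, dtype=np.float32)
    background = np.asarray(background, dtype=np.float32)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame - background)
    if diff.max() <= 0 or np.unique(diff).size < 2:
        return np.zeros(frame.shape, dtype=bool)
    mask = diff > threshold_otsu(diff)
    if config.opening_radius > 0:
        mask = ndimage.binary_opening(mask, disk(config.opening_radius))
    if config.closing_radius > 0:
        mask = ndimage.binary_closing(mask, disk(config.closing_radius))
    if config.min_fragment_px > 0:
        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < config.min_fragment_px)
            mask &= ~np.isin(labels, small[small > 0])
    return mask


def growth_trace(
    stack: FrameStack,
    n_worms: int,
    background: np.ndarray | None = None,
    config: SegmentationConfig = SegmentationConfig(),
) -> GrowthTrace:
    """Segment every frame and report total/normalized area over time."""
    if n_worms < 1:
        raise ValueError(f"n_worms must be >= 1, got {n_worms}")
    if background is None:
        background = estimate_background(stack)
    total = np.empty(stack.n_frames, dtype=float)
    for f in range(stack.n_frames):
        total[f] = int(segment_worms(stack.frames[f], background, config).sum())
    return GrowthTrace(times=stack.times, total_area=total, n_worms=n_worms)


def fit_growth_sigmoid(trace: GrowthTrace) -> GrowthFit:
    """Least-squares 4-parameter logistic fit of the normalized-area trace.

    Non-convergence is flagged, never silent; a flat trace (amplitude below
    0.1 % of its level) returns a degenerate fit with rate 0.
    """
    t = trace.times
    y = trace.normalized_area
    if len(t) < 6:
        raise ValueError(f"need >= 6 time points for a 4-parameter fit, got {len(t)}")
    lo, hi = float(y.min()), float(y.max())
    amplitude = hi - lo
    if amplitude <= 1e-3 * max(abs(hi), 1.0):
        level = float(y.mean())
        return GrowthFit(
            lower=level,
            upper=level,
            rate=0.0,
            midpoint=float(t[len(t) // 2]),
            rmse=float(np.sqrt(np.mean((y - level) ** 2))),
            converged=True,
            degenerate=True,
            fitted=np.full_like(y, level),
        )
    mid_guess = float(t[np.argmin(np.abs(y - (lo + hi) / 2.0))])
    span = float(t[-1] - t[0])
    p0 = (lo, hi, 4.0 / max(span / 2.0, 1e-9), mid_guess)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _logistic,
                t,
                y,
                p0=p0,
                maxfev=20000,
                bounds=(
                    [-np.inf, -np.inf, 0.0, t[0] - span],
                    [np.inf, np.inf, np.inf, t[-1] + span],
                ),
            )
        fitted = _logistic(t, *popt)
        rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
        return GrowthFit(
            lower=float(popt[0]),
            upper=float(popt[1]),
            rate=float(popt[2]),
            midpoint=float(popt[3]),
            rmse=rmse,
            converged=True,
            degenerate=False,
            fitted=fitted,
        )
    except RuntimeError:
        return GrowthFit(
            lower=lo,
            upper=hi,
            rate=float("nan"),
            midpoint=float("nan"),
            rmse=float("nan"),
            converged=False,
            degenerate=False,
            fitted=np.full_like(y, np.nan),
        )


@dataclass
class EggPhenotypes:
    """Egg-release phenotypes of one chamber.

    ``t_first_egg`` is minutes after the stack's time origin (L4 onset);
    ``release_rate`` is eggs·h⁻¹·worm⁻¹ averaged over the first two hours
    after the first laying event.  ``no_egg_laying`` mirrors chambers where
    no egg is ever observed (all phenotype values are NaN there).
    """

    t_first_egg: float
    eggs_at_first: float
    eggs_at_first_plus_1h: float
    eggs_per_worm: float
    release_rate: float
    no_egg_laying: bool = False


def egg_phenotypes(
    egg_counts: np.ndarray,
    times: np.ndarray,
    n_worms: int,
) -> EggPhenotypes:
    """Derive egg phenotypes from a cumulative per-frame egg count series.

    The first-egg time is the earliest frame with a positive count; the
    count "one hour later" is read at the nearest frame at or after +60 min
    (clipped to the last frame); the release rate divides the count gained
    over the two hours after the first egg (again clipped to the series end)
    by 2 h and by the worm count.
    """
    counts = np.asarray(egg_counts, dtype=float)
    times = np.asarray(times, dtype=float)
    if counts.shape != times.shape:
        raise ValueError("egg_counts and times must align")
    if np.any(np.diff(counts) < 0):
        raise ValueError("egg counts must be cumulative (non-decreasing)")
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    positive = np.flatnonzero(counts > 0)
    if positive.size == 0:
        nan = float("nan")
        return EggPhenotypes(nan, nan, nan, nan, nan, no_egg_laying=True)
    i0 = int(positive[0])
    t0 = float(times[i0])
    at_first = float(counts[i0])
    i1h = np.searchsorted(times, t0 + 60.0)
    i1h = min(int(i1h), len(times) - 1)
    at_plus_1h = float(counts[i1h])
    i2h = np.searchsorted(times, t0 + 120.0)
    i2h = min(int(i2h), len(times) - 1)
    rate = (float(counts[i2h]) - at_first) / 2.0 / n_worms
    return EggPhenotypes(
        t_first_egg=t0,
        eggs_at_first=at_first,
        eggs_at_first_plus_1h=at_plus_1h,
        eggs_per_worm=at_plus_1h / n_worms,
        release_rate=rate,
    )
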