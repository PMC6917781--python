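"""Trap–incubator localization in serpentine images and patch cropping.

Localization is normalized cross-correlation against a template *synthesized
from the device geometry* (the chip features are known by design, so no
training data is needed): correlation peaks above a threshold are kept after
non-maximum suppression at half the unit pitch and ordered along the
serpentine.  Fixed-size square patches (default 200×200 px) are then cropped
around the trap and incubator centres of each site for the embryo analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template, peak_local_max

from . import imgen
from .geometry import TrapGeometry
from .io_core import FrameStack

__all__ = [
    "TrapSite",
    "LocalizationResult",
    "synthesize_template",
    "locate_traps",
    "crop_patches",
    "sites_to_csv",
    "sites_from_csv",
]

DEFAULT_PATCH_SIZE = 200


@dataclass(frozen=True)
class TrapSite:
    """One localized trap–incubator unit.

    ``intersection`` is the (row, col) of the trap/incubator midpoint;
    patch origins are top-left corners of the square analysis windows.
    """

    index: int
    intersection: tuple[int, int]
    trap_patch_origin: tuple[int, int]
    incubator_patch_origin: tuple[int, int]


@dataclass
class LocalizationResult:
    """Sites plus the raw correlation peak map for diagnostics (the map is
    returned even when no site passes the threshold)."""

    sites: list[TrapSite]
    correlation: np.ndarray
    threshold: float


def synthesize_template(geometry: TrapGeometry) -> np.ndarray:
    """Render one noise-free unit from the geometry and crop the matching
    template around its intersection."""
    spec = imgen.SceneSpec(rng_seed=0, noise_sd=0.0, illum_gradient=0.0, n_frames=2)
    stack, truth = imgen.render_serpentine(spec, geometry, n_traps=1)
    img = stack.frames[0].astype(np.float32)
    (row, col) = truth.trap_coords[0]
    th, tw = geometry.template_shape()
    r0, c0 = row - th // 2, col - tw // 2
    return img[r0 : r0 + th, c0 : c0 + tw].copy()


def _patch_origins(
    intersection: tuple[int, int], geometry: TrapGeometry, size: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    tr, tc = geometry.trap_center(intersection)
    ir, ic = geometry.incubator_center(intersection)
    half = size // 2
    return (tr - half, tc - half), (ir - half, ic - half)


def locate_traps(
    image: np.ndarray | FrameStack,
    geometry: TrapGeometry,
    threshold: float = 0.6,
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> LocalizationResult:
    """Find trap–incubator units by template matching.

    Peaks of the normalized cross-correlation above ``threshold`` are kept
    with non-maximum suppression at half the trap pitch; sites are ordered
    along the serpentine (by column).  Returns an empty site list — with the
    peak map for inspection — when nothing passes.
    """
    if isinstance(image, FrameStack):
        image = image.frames[0]
    img = np.asarray(image, dtype=np.float32)
    template = synthesize_template(geometry)
    corr = match_template(img, template, pad_input=True)
    peaks = peak_local_max(
        corr,
        min_distance=max(1, geometry.pitch // 2),
        threshold_abs=threshold,
        exclude_border=False,
    )
    order = np.argsort(peaks[:, 1], kind="stable") if len(peaks) else []
    sites: list[TrapSite] = []
    for i, k in enumerate(order):
        inter = (int(peaks[k, 0]), int(peaks[k, 1]))
        trap_o, inc_o = _patch_origins(inter, geometry, patch_size)
        sites.append(
            TrapSite(
                index=i,
                intersection=inter,
                trap_patch_origin=trap_o,
                incubator_patch_origin=inc_o,
            )
        )
    return LocalizationResult(sites=sites, correlation=corr, threshold=threshold)


def crop_patches(
    stack: FrameStack,
    site: TrapSite,
    size: int = DEFAULT_PATCH_SIZE,
) -> tuple[FrameStack, FrameStack]:
    """Crop the per-frame trap and incubator windows of one site.

    Both windows are ``size``×``size``; an out-of-bounds window raises,
    naming the site index.
    """
    try:
        trap = stack.window(site.trap_patch_origin, size)
        incubator = stack.window(site.incubator_patch_origin, size)
    except ValueError as exc:
        raise ValueError(f"site {site.index}: {exc}") from exc
    return trap, incubator


def sites_to_csv(sites: list[TrapSite], path) -> None:
    pd.DataFrame(
        {
            "index": [s.index for s in sites],
            "row": [s.intersection[0] for s in sites],
            "col": [s.intersection[1] for s in sites],
        }
    ).to_csv(path, index=False)


def sites_from_csv(path, geometry: TrapGeometry, patch_size: int = DEFAULT_PATCH_SIZE) -> list[TrapSite]:
    df = pd.read_csv(path)
    sites = []
    for _, row in df.iterrows():
        inter = (int(row["row"]), int(row["col"]))
        trap_o, inc_o = _patch_origins(inter, geometry, patch_size)
        sites.append(
            TrapSite(
                index=int(row["index"]),
                intersection=inter,
                trap_patch_origin=trap_o,
                incubator_patch_origin=inc_o,
            )
        )
    return sites
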