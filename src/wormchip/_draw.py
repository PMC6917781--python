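"""Low-level rasterization helpers shared by the synthetic renderers.

Everything here is pure array construction: ellipses with soft (blurred)
edges, spatially correlated texture fields, and tube masks built from a
centreline polyline via a distance transform.  Renders work in float and are
finalized to the package-wide 16-bit unsigned convention at the end.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

U16_MAX = 65535.0


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi: tuple[float, float],
) -> np.ndarray:
    """Boolean ellipse; ``semi`` are (row, col) semi-axes."""
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return (rr / semi[0]) ** 2 + (cc / semi[1]) ** 2 <= 1.0


def rect_mask(
    shape: tuple[int, int],
    r0: float,
    r1: float,
    c0: float,
    c1: float,
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    r0i, r1i = max(0, int(round(r0))), min(shape[0], int(round(r1)))
    c0i, c1i = max(0, int(round(c0))), min(shape[1], int(round(c1)))
    if r1i > r0i and c1i > c0i:
        out[r0i:r1i, c0i:c1i] = True
    return out


def soft_alpha(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Blurred [0, 1] coverage map of a boolean mask (sigma=0 → hard edge)."""
    alpha = mask.astype(np.float32)
    if sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, sigma)
    return alpha


def composite(img: np.ndarray, alpha: np.ndarray, value: float) -> np.ndarray:
    """Alpha-blend a flat value into ``img`` in place and return it."""
    img *= 1.0 - alpha
    img += alpha * value
    return img


def smooth_field(
    shape: tuple[int, int],
    rng: np.random.Generator,
    corr_px: float,
    sd: float,
) -> np.ndarray:
    """Zero-mean Gaussian texture with ~``corr_px`` correlation length and unit-
    calibrated standard deviation ``sd``."""
    field = rng.standard_normal(shape).astype(np.float32)
    if corr_px > 0:
        field = ndimage.gaussian_filter(field, corr_px)
        field /= max(field.std(), 1e-12)
    return field * sd


def polyline_distance(
    shape: tuple[int, int],
    points: np.ndarray,
    pad: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Euclidean distance to a rasterized polyline, restricted to its padded
    bounding box.

    Returns ``(dist, (r0, c0))`` where ``dist`` covers the box with origin
    ``(r0, c0)`` in image coordinates.  Points outside the image are clipped.
    """
    pts = np.asarray(points, dtype=float)
    r0 = max(0, int(np.floor(pts[:, 0].min())) - pad)
    r1 = min(shape[0], int(np.ceil(pts[:, 0].max())) + pad + 1)
    c0 = max(0, int(np.floor(pts[:, 1].min())) - pad)
    c1 = min(shape[1], int(np.ceil(pts[:, 1].max())) + pad + 1)
    box = np.ones((r1 - r0, c1 - c0), dtype=bool)
    ri = np.clip(np.round(pts[:, 0]).astype(int) - r0, 0, box.shape[0] - 1)
    ci = np.clip(np.round(pts[:, 1]).astype(int) - c0, 0, box.shape[1] - 1)
    box[ri, ci] = False
    dist = ndimage.distance_transform_edt(box)
    return dist, (r0, c0)


def tube_mask_exact_area(
    shape: tuple[int, int],
    points: np.ndarray,
    area: int,
    halfwidth_hint: float,
) -> np.ndarray:
    """Tube of exactly ``area`` pixels around a centreline polyline.

    The ``area`` pixels closest to the polyline (within a padded bounding
    box) are selected, which makes the rendered object's pixel count equal
    the requested ground-truth area *exactly* while keeping a smooth tubular
    outline.  Ties are broken by flat index, deterministically.
    """
    pad = int(np.ceil(halfwidth_hint * 2)) + 3
    dist, (r0, c0) = polyline_distance(shape, points, pad)
    flat = dist.ravel()
    if area > flat.size:
        raise ValueError(f"requested area {area} exceeds drawable region {flat.size}")
    order = np.argsort(flat, kind="stable")[:area]
    box = np.zeros(dist.shape, dtype=bool)
    box.ravel()[order] = True
    out = np.zeros(shape, dtype=bool)
    out[r0 : r0 + box.shape[0], c0 : c0 + box.shape[1]] = box
    return out


def tube_mask(
    shape: tuple[int, int],
    points: np.ndarray,
    halfwidth: float,
) -> np.ndarray:
    """Tube of fixed half-width around a centreline polyline (round caps)."""
    pad = int(np.ceil(halfwidth)) + 3
    dist, (r0, c0) = polyline_distance(shape, points, pad)
    box = dist <= halfwidth
    out = np.zeros(shape, dtype=bool)
    out[r0 : r0 + box.shape[0], c0 : c0 + box.shape[1]] = box
    return out


def illumination(shape: tuple[int, int], gradient: float) -> np.ndarray:
    """Multiplicative linear illumination ramp across image width.

    ``gradient`` is the fractional intensity change per image width; the ramp
    is centred so the image mean is preserved.
    """
    w = shape[1]
    ramp = 1.0 + gradient * (np.arange(w, dtype=np.float32) / max(w - 1, 1) - 0.5)
    return np.broadcast_to(ramp[None, :], shape)


def finalize_u16(
    img: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add i.i.d. Gaussian read noise, clip to the 16-bit range, cast."""
    out = np.asarray(img, dtype=np.float32)
    if noise_sd > 0:
        out = out + rng.standard_normal(out.shape, dtype=np.float32) * np.float32(noise_sd)
    np.clip(out, 0.0, U16_MAX, out=out)
    return out.astype(np.uint16)
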