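"""Device geometry of the embryo serpentine.

The chip's serpentine carries a row of trap–incubator units: each unit pairs a
wing-tipped *embryo trap* (which confines a single embryo for time-lapse
imaging) with an adjacent *incubator* lumen that serves as the fluorescence
background reference.  Both the synthetic renderer and the template-based
localizer consume the same :class:`TrapGeometry`, so a template synthesized
from the geometry needs no training data and localization can be validated
against render-time ground truth.

All lengths are in pixels at the 20× imaging scale (0.8 µm/px default).  The
*intersection* of a unit is the point midway between the incubator and trap
lumen centres — the coordinate the localizer reports and patch cropping is
anchored to.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import yaml

__all__ = ["TrapGeometry", "load_geometry", "save_geometry"]


@dataclass(frozen=True)
class TrapGeometry:
    """Geometry of a serpentine of trap–incubator units.

    Attributes
    ----------
    n_units
        Number of trap–incubator units along the serpentine (25 on the chip).
    pitch
        Centre-to-centre spacing of consecutive units along the channel, px.
    margin
        Blank border around the serpentine render, px.
    unit_offset
        Row distance from the intersection point to each lumen centre: the
        incubator sits ``unit_offset`` above, the trap ``unit_offset`` below.
    incubator_semi / trap_semi
        Semi-axes ``(row, col)`` of the incubator and trap lumen ellipses.
    embryo_semi
        Semi-axes of the embryo footprint as rendered/confined in the trap
        (≈50×30 µm egg at 0.8 µm/px).  The analysis mask is this ellipse
        eroded by ``mask_margin`` px so it never touches PDMS walls.
    mask_margin
        Erosion margin of the analysis mask inside the embryo footprint, px.
    mask_shift
        Row shift mapping the trap-centred mask onto the incubator lumen
        (equals ``2 * unit_offset`` for the default layout), px.
    neck_halfwidth
        Half-width of the narrow neck connecting incubator and trap, px.
    channel_halfheight
        Half-height of the flow channel band through the incubators, px.
    wing_len / wing_halfwidth
        Size of the two wing-shaped protrusions at the trap tip, px.
    """

    n_units: int = 25
    pitch: int = 120
    margin: int = 100
    unit_offset: int = 28
    incubator_semi: tuple[int, int] = (24, 34)
    trap_semi: tuple[int, int] = (21, 33)
    embryo_semi: tuple[int, int] = (19, 31)
    mask_margin: int = 1
    mask_shift: int = 56
    neck_halfwidth: int = 4
    channel_halfheight: int = 14
    wing_len: int = 10
    wing_halfwidth: int = 3

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.pitch <= 2 * self.incubator_semi[1]:
            raise ValueError("pitch must exceed the incubator width")
        er, ec = self.embryo_semi
        tr, tc = self.trap_semi
        if er > tr or ec > tc:
            raise ValueError("embryo footprint must fit inside the trap lumen")

    # -- derived layout -----------------------------------------------------

    def serpentine_shape(self, n_units: int | None = None) -> tuple[int, int]:
        n = self.n_units if n_units is None else n_units
        height = 2 * self.margin + 2 * (self.unit_offset + self.trap_semi[0])
        width = 2 * self.margin + (n - 1) * self.pitch
        return height, width

    def intersections(self, n_units: int | None = None) -> list[tuple[int, int]]:
        """Ground-truth intersection coordinates, ordered along the serpentine."""
        n = self.n_units if n_units is None else n_units
        height, _ = self.serpentine_shape(n)
        row = height // 2
        return [(row, self.margin + i * self.pitch) for i in range(n)]

    def trap_center(self, intersection: tuple[int, int]) -> tuple[int, int]:
        return intersection[0] + self.unit_offset, intersection[1]

    def incubator_center(self, intersection: tuple[int, int]) -> tuple[int, int]:
        return intersection[0] - self.unit_offset, intersection[1]

    def template_shape(self) -> tuple[int, int]:
        rows = 2 * (self.unit_offset + self.trap_semi[0]) + 6
        cols = 2 * self.incubator_semi[1] + 6
        return rows, cols


def load_geometry(path: str | os.PathLike) -> TrapGeometry:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    for key in ("incubator_semi", "trap_semi", "embryo_semi"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return TrapGeometry(**doc)


def save_geometry(geometry: TrapGeometry, path: str | os.PathLike) -> None:
    doc = asdict(geometry)
    for key in ("incubator_semi", "trap_semi", "embryo_semi"):
        doc[key] = list(doc[key])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
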