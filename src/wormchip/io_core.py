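"""Image-stack and experiment-metadata I/O.

The whole pipeline moves data through three containers:

* :class:`FrameStack` — an ordered single-channel time-lapse (brightfield or
  fluorescence) with per-frame acquisition times in minutes and a pixel
  calibration in µm/px.  Stacks are stored on disk as multi-page TIFF, one
  file per channel; timestamps travel in a sidecar config, not in TIFF
  metadata.
* :class:`ExperimentLayout` — the plate map of a chip run: one record per
  microfluidic lane giving the treatment condition (MET/OMT/OET/CNT), the
  doxycycline dose, the number of mother worms cultured in the chamber, and
  the paths of the image files belonging to that lane.
* :class:`PhenotypeTable` — the tidy per-individual output schema consumed by
  :mod:`wormchip.stats`.  One row per (individual, phenotype).

Pixel coordinates are 0-based ``(row, col)`` with origin at the top-left;
times are minutes since experiment onset throughout the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "BRIGHTFIELD",
    "FLUORESCENCE",
    "CHANNELS",
    "CONDITIONS",
    "DOSES",
    "FrameStack",
    "LaneLayout",
    "ExperimentLayout",
    "LayoutError",
    "PhenotypeTable",
    "PHENOTYPE_COLUMNS",
    "load_stack",
    "save_stack",
    "load_layout",
    "validate_layout",
]

BRIGHTFIELD = "brightfield"
FLUORESCENCE = "fluorescence"
CHANNELS = (BRIGHTFIELD, FLUORESCENCE)

#: Treatment conditions: Mother-and-Embryo Treated (continuous drug), Only-Mother
#: Treated (15 h exposure), Only-Embryo Treated, and untreated Control.
CONDITIONS = ("MET", "OMT", "OET", "CNT")

#: Doxycycline doses used on the platform, µg/mL.
DOSES = (0, 15, 30, 60)


@dataclass
class FrameStack:
    """An ordered stack of single-channel grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.  16-bit unsigned is the
        package-wide convention for rendered/acquired images, but any
        grayscale dtype is accepted.
    times
        Acquisition time of each frame in minutes since experiment onset;
        strictly increasing, one entry per frame.
    channel
        Either ``"brightfield"`` or ``"fluorescence"``.
    pixel_size
        Lateral calibration, µm/px.
    """

    frames: np.ndarray
    times: np.ndarray
    channel: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, h, w) grayscale stack, got ndim={self.frames.ndim}"
            )
        if self.times.ndim != 1 or len(self.times) != len(self.frames):
            raise ValueError(
                f"times length ({len(self.times)}) must match frame count "
                f"({len(self.frames)})"
            )
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def window(self, origin: tuple[int, int], size: int) -> "FrameStack":
        """Return the sub-stack cropped to a square window (no copy checks)."""
        r, c = origin
        h, w = self.frame_shape
        if r < 0 or c < 0 or r + size > h or c + size > w:
            raise ValueError(
                f"window origin={origin} size={size} exceeds frame shape {(h, w)}"
            )
        return replace(self, frames=self.frames[:, r : r + size, c : c + size])


def load_stack(
    path: str | os.PathLike,
    channel: str,
    times: Sequence[float],
    pixel_size: float,
) -> FrameStack:
    """Read a multi-page grayscale TIFF and pair its pages with timestamps.

    Raises
    ------
    ValueError
        If the page count does not match ``len(times)`` (both counts are
        named in the message) or the file is not single-channel grayscale.
    """
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel grayscale stack, got shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(f"{path}: looks like a color image (shape {arr.shape})")
    times = np.asarray(times, dtype=float)
    if len(times) != len(arr):
        raise ValueError(
            f"{path}: page count ({len(arr)}) does not match supplied time count "
            f"({len(times)})"
        )
    return FrameStack(frames=arr, times=times, channel=channel, pixel_size=pixel_size)


def save_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF (lossless; round-trips exactly)."""
    tifffile.imwrite(os.fspath(path), stack.frames)


# ---------------------------------------------------------------------------
# Experiment layout
# ---------------------------------------------------------------------------


class LayoutError(ValueError):
    """Raised when an experiment layout fails validation."""


@dataclass
class LaneLayout:
    """One microfluidic lane: condition, dose and the image files it produced."""

    lane_id: str
    condition: str
    dose: int
    worm_count: int = 0
    chamber_stack: str | None = None
    serpentine_image: str | None = None
    trap_stacks: tuple[str, ...] = ()


@dataclass
class ExperimentLayout:
    lanes: list[LaneLayout] = field(default_factory=list)


def load_layout(path: str | os.PathLike) -> ExperimentLayout:
    """Parse a YAML layout file into an :class:`ExperimentLayout` (unvalidated)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lanes = []
    for entry in doc.get("lanes", []):
        lanes.append(
            LaneLayout(
                lane_id=str(entry["lane_id"]),
                condition=entry["condition"],
                dose=int(entry["dose"]),
                worm_count=int(entry.get("worm_count", 0)),
                chamber_stack=entry.get("chamber_stack"),
                serpentine_image=entry.get("serpentine_image"),
                trap_stacks=tuple(entry.get("trap_stacks", ())),
            )
        )
    return ExperimentLayout(lanes=lanes)


def validate_layout(
    layout: ExperimentLayout,
    base_dir: str | os.PathLike | None = None,
    check_paths: bool = True,
) -> ExperimentLayout:
    """Check enumerations and referenced paths; return the layout unchanged.

    Raises
    ------
    LayoutError
        Naming the offending lane for an unknown condition/dose, a chamber
        stack without a positive worm count, trap stacks declared without a
        serpentine image, or an unresolvable path.
    """
    for lane in layout.lanes:
        where = f"lane {lane.lane_id!r}"
        if lane.condition not in CONDITIONS:
            raise LayoutError(
                f"{where}: unknown condition {lane.condition!r}; expected one of {CONDITIONS}"
            )
        if lane.dose not in DOSES:
            raise LayoutError(
                f"{where}: unknown dose {lane.dose!r} µg/mL; expected one of {DOSES}"
            )
        if lane.chamber_stack is not None and lane.worm_count < 1:
            raise LayoutError(
                f"{where}: declares a chamber stack but worm_count={lane.worm_count}"
            )
        if lane.trap_stacks and lane.serpentine_image is None:
            raise LayoutError(
                f"{where}: declares trap stacks but no serpentine image for localization"
            )
        if check_paths:
            for p in filter(
                None,
                (lane.chamber_stack, lane.serpentine_image, *lane.trap_stacks),
            ):
                full = os.path.join(base_dir, p) if base_dir is not None else p
                if not os.path.exists(full):
                    raise LayoutError(f"{where}: referenced path not found: {p}")
    return layout


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "individual_id",
    "lane",
    "condition",
    "dose",
    "phenotype_name",
    "value",
    "units",
]


class PhenotypeTable:
    """Tidy per-individual phenotype records, one row per (individual, phenotype).

    This is the only schema the statistics stage consumes; every upstream
    module emits it.  ``individual_id`` identifies a worm, embryo or L1 within
    its lane; ``value`` must be finite.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        df = df[PHENOTYPE_COLUMNS].copy()
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValueError("phenotype table contains non-finite values")
        dup = df.duplicated(subset=["individual_id", "lane", "phenotype_name"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (individual, phenotype) rows in table"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "PhenotypeTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, index=False)

    def concat(self, other: "PhenotypeTable") -> "PhenotypeTable":
        return PhenotypeTable(pd.concat([self.df, other.df], ignore_index=True))
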