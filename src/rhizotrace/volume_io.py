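"""Reading image stacks and seed configurations; writing labelled root volumes.

A micro-CT scan is handled as an ordered sequence of 2D greyscale
cross-sections (slice 0 = top of the soil column, matching the top-down
tracking direction). Coordinates are 0-based ``(slice, row, col)``.

Accepted inputs are a multi-page TIFF or a directory of equally sized
single-slice TIFF/PNG images; slice order inside a directory is the sorted
filename order, independent of how the filesystem lists entries. Output is a
multi-page 16-bit TIFF label stack plus one binary mask stack per plant,
round-tripping losslessly through :func:`read_labels`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "SeedEntry",
    "SeedConfig",
    "RootVolume",
    "read_stack",
    "read_seeds",
    "write_labels",
    "read_labels",
]

_STACK_SUFFIXES = {".tif", ".tiff", ".png"}


class FormatError(ValueError):
    """Raised when input data violate a structural format requirement."""


@dataclass
class ImageStack:
    """Ordered greyscale slices with uniform shape.

    ``slices`` is a (depth, height, width) array; ``pixel_size`` is an
    optional physical scale in micrometres per pixel, carried as metadata
    only.
    """

    slices: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim == 2:
            self.slices = self.slices[np.newaxis]
        if self.slices.ndim != 3:
            raise FormatError(
                f"stack must be a (depth, height, width) array, got ndim={self.slices.ndim}"
            )
        if self.slices.shape[0] < 1:
            raise FormatError("stack must contain at least one slice")
        if not np.all(np.isfinite(self.slices.astype(np.float64, copy=False))):
            raise FormatError("stack intensities must be finite")
        if self.slices.min() < 0:
            raise FormatError("stack intensities must be non-negative")

    @property
    def depth(self) -> int:
        return self.slices.shape[0]

    @property
    def height(self) -> int:
        return self.slices.shape[1]

    @property
    def width(self) -> int:
        return self.slices.shape[2]

    def __len__(self) -> int:
        return self.depth


@dataclass(frozen=True)
class SeedEntry:
    plant_id: int
    points: tuple[tuple[int, int, int], ...]


@dataclass
class SeedConfig:
    """Seed points grouped per plant; a plant may own several seed points."""

    entries: list[SeedEntry]

    def __post_init__(self) -> None:
        ids = [e.plant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate plant ids in seed config: {ids}")
        for e in self.entries:
            if e.plant_id <= 0:
                raise ValueError("plant ids must be positive integers (0 = background)")
            if not e.points:
                raise ValueError(f"plant {e.plant_id} has no seed points")

    @property
    def plant_ids(self) -> list[int]:
        return [e.plant_id for e in self.entries]

    def validate_against(self, stack: ImageStack) -> None:
        """Check every seed point lies within the stack bounds."""
        for e in self.entries:
            for (z, y, x) in e.points:
                if not (0 <= z < stack.depth and 0 <= y < stack.height and 0 <= x < stack.width):
                    raise ValueError(
                        f"seed point {(z, y, x)} of plant {e.plant_id} outside "
                        f"stack bounds {(stack.depth, stack.height, stack.width)}"
                    )


@dataclass
class RootVolume:
    """Per-plant labelled voxel output: one integer label per plant, 0 = background."""

    labels: np.ndarray
    provenance: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (depth, height, width) array")

    @property
    def plant_ids(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]


def _read_single(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_stack(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Read a multi-page TIFF or a directory of single-slice images.

    Directory entries are taken in sorted filename order so slice order is
    stable regardless of filesystem listing order. All slices must share one
    shape; a mismatch raises :class:`FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.is_file() and p.suffix.lower() in _STACK_SUFFIXES
        )
        if not files:
            raise ValueError(f"no TIFF/PNG slices found in directory {path}")
        slices = []
        for f in files:
            img = _read_single(f)
            if img.ndim == 3 and img.shape[-1] in (3, 4):  # RGB(A) -> luminance
                img = img[..., :3].mean(axis=-1)
            if img.ndim != 2:
                raise FormatError(f"{f} is not a single 2D slice (shape {img.shape})")
            if slices and img.shape != slices[0].shape:
                raise FormatError(
                    f"slice shape mismatch: {f} has {img.shape}, "
                    f"expected {slices[0].shape}"
                )
            slices.append(img)
        return ImageStack(np.stack(slices), pixel_size=pixel_size)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    return ImageStack(data, pixel_size=pixel_size)


def read_seeds(path: str | Path, stack: ImageStack | None = None) -> SeedConfig:
    """Read a YAML seed configuration.

    Two equivalent layouts are accepted::

        plants:
          1: [[0, 60, 60]]
          2: [[0, 200, 200], [0, 240, 100]]

        plants:
          - id: 1
            points: [[0, 60, 60]]
          - id: 2
            points: [[0, 200, 200]]

    Points are 0-based ``[slice, row, col]``. Duplicate plant ids and (when a
    stack is given) out-of-bounds points raise ``ValueError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "plants" not in raw:
        raise ValueError("seed config must be a mapping with a 'plants' key")
    plants = raw["plants"]
    entries: list[SeedEntry] = []
    if isinstance(plants, dict):
        items = [(int(k), v) for k, v in plants.items()]
    elif isinstance(plants, list):
        items = [(int(d["id"]), d["points"]) for d in plants]
    else:
        raise ValueError("'plants' must be a mapping or a list of {id, points}")
    for plant_id, pts in items:
        if not isinstance(pts, Sequence) or not pts:
            raise ValueError(f"plant {plant_id}: points must be a non-empty list")
        points = []
        for p in pts:
            if len(p) != 3:
                raise ValueError(f"seed point {p} must be [slice, row, col]")
            z, y, x = (int(v) for v in p)
            if z < 0 or y < 0 or x < 0:
                raise ValueError(f"seed point {(z, y, x)} has negative coordinates")
            points.append((z, y, x))
        entries.append(SeedEntry(plant_id, tuple(points)))
    config = SeedConfig(entries)
    if stack is not None:
        config.validate_against(stack)
    return config


def write_labels(volume: RootVolume, path: str | Path) -> None:
    """Write ``labels.tif`` (multi-page uint16), per-plant binary masks and provenance.

    The label stack round-trips bit-exactly through :func:`read_labels`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = volume.labels.astype(np.uint16)
    tifffile.imwrite(path / "labels.tif", labels, photometric="minisblack")
    for pid in volume.plant_ids:
        mask = (labels == pid).astype(np.uint8) * 255
        tifffile.imwrite(path / f"plant_{pid}_mask.tif", mask, photometric="minisblack")
    if volume.provenance:
        with open(path / "provenance.json", "w") as fh:
            json.dump({str(k): v for k, v in volume.provenance.items()}, fh, indent=2)


def read_labels(path: str | Path) -> RootVolume:
    """Read a label volume previously written by :func:`write_labels`."""
    path = Path(path)
    labels = tifffile.imread(path / "labels.tif")
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    prov_file = path / "provenance.json"
    provenance = {}
    if prov_file.exists():
        with open(prov_file) as fh:
            provenance = {int(k): v for k, v in json.load(fh).items()}
    return RootVolume(labels, provenance)
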