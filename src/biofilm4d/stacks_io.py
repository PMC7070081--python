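"""Image-stack data model and TIFF I/O.

A confocal acquisition is represented as a 4D dataset: for each time point
and fluorescence channel there is one 3D voxel grid (:class:`ImageStack`).
Arrays are indexed ``[z, y, x]`` with Z index 0 at the *top* of the stack
(the slice nearest the objective), matching a top-to-bottom confocal scan.

Physical calibration never comes from TIFF tags: plain multi-page TIFF has
no reliable voxel-size metadata, so geometry (pixel pitch, Z step, frame
interval) is always supplied explicitly, typically from a sidecar YAML/JSON
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

CHANNELS = ("reflection", "bacteria", "organism2", "eps")


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration of one acquisition.

    Parameters
    ----------
    dx, dy : float
        Lateral pixel pitch in µm/pixel.
    dz : float
        Z step between slices in µm.
    frame_interval : float
        Nominal time between frames in minutes.
    """

    dx: float
    dy: float
    dz: float
    frame_interval: float = 20.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz", "frame_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz


@dataclass
class ImageStack:
    """One channel's 3D intensity grid at a single time point.

    ``values`` is indexed ``[z, y, x]``; under ``z_orientation='top'``
    index 0 is the slice nearest the objective.
    """

    values: np.ndarray
    geometry: VoxelGeometry
    channel: str = "bacteria"
    z_orientation: str = "top"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("stack values must be a 3D array")
        if self.values.size == 0:
            raise ValueError("stack must be non-empty")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.z_orientation not in ("top", "bottom"):
            raise ValueError("z_orientation must be 'top' or 'bottom'")
        if np.issubdtype(self.values.dtype, np.integer):
            info = np.iinfo(self.values.dtype)
            if self.values.min() < info.min or self.values.max() > info.max:
                raise ValueError("intensities exceed declared bit depth")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (Z, Y, X)

    def with_values(self, values: np.ndarray) -> "ImageStack":
        return replace(self, values=values)


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned crop window; 0-based, half-open pixel intervals."""

    x_range: tuple[int, int]
    y_range: tuple[int, int]
    z_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name, rng in (("x_range", self.x_range), ("y_range", self.y_range),
                          ("z_range", self.z_range)):
            if rng is None:
                continue
            lo, hi = rng
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be non-empty and non-negative, got {rng}")

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        nz, ny, nx = shape
        if self.x_range[1] > nx or self.y_range[1] > ny:
            raise ValueError(f"roi {self} exceeds stack extent {shape}")
        if self.z_range is not None and self.z_range[1] > nz:
            raise ValueError(f"roi z_range {self.z_range} exceeds {nz} slices")


@dataclass
class TimeLapse:
    """Ordered frames of a time-lapse acquisition.

    Each frame is ``(time_minutes, {channel: ImageStack})``.  ``t0_index``
    marks the pre-flow baseline scan.
    """

    frames: list[tuple[float, dict[str, ImageStack]]]
    t0_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("timelapse must contain at least one frame")
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.t0_index < len(self.frames):
            raise ValueError("t0_index out of range")
        shapes = {s.shape[1:] for _, chans in self.frames for s in chans.values()}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share XY extent, got {shapes}")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.frames]

    def channel_series(self, channel: str) -> Iterator[tuple[float, ImageStack]]:
        for t, chans in self.frames:
            if channel in chans:
                yield t, chans[channel]


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, geometry: VoxelGeometry,
               channel: str = "bacteria", z_orientation: str = "top") -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Page *k* maps to Z index *k* under the declared ``z_orientation``.
    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    non-grayscale or inconsistently shaped pages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise ValueError(f"{path}: inconsistent page shapes {shapes}")
    if any(p.ndim != 2 for p in pages):
        raise ValueError(f"{path}: non-grayscale pages (expected single-sample 2D pages)")
    values = np.stack(pages, axis=0)
    return ImageStack(values, geometry, channel=channel, z_orientation=z_orientation)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a lossless multi-page TIFF, one page per Z slice."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.values))
    return path


# ---------------------------------------------------------------------------
# Geometry-preserving views
# ---------------------------------------------------------------------------

def crop_region(obj: ImageStack | TimeLapse, roi: RegionOfInterest):
    """Crop a stack or a whole time lapse to an ROI.

    Geometry is unchanged (a crop does not recalibrate pixels); for a
    time lapse the time axis is untouched and every channel is cropped.
    """
    if isinstance(obj, TimeLapse):
        frames = [(t, {c: crop_region(s, roi) for c, s in chans.items()})
                  for t, chans in obj.frames]
        return TimeLapse(frames, t0_index=obj.t0_index)
    roi.validate_against(obj.shape)
    zr = roi.z_range or (0, obj.shape[0])
    values = obj.values[zr[0]:zr[1],
                        roi.y_range[0]:roi.y_range[1],
                        roi.x_range[0]:roi.x_range[1]]
    return obj.with_values(values.copy())


def zproject_max(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity Z projection: per (x, y), the brightest voxel along Z."""
    return np.asarray(stack.values).max(axis=0)


# ---------------------------------------------------------------------------
# Manifest loading (sidecar metadata)
# ---------------------------------------------------------------------------

def load_timelapse(manifest: Mapping, base_dir: str | Path | None = None) -> TimeLapse:
    """Assemble a :class:`TimeLapse` from a manifest mapping.

    Expected keys::

        geometry: {dx, dy, dz, frame_interval}
        t0_index: int (default 0)
        frames:   [{time: minutes, channels: {name: tiff path}}, ...]

    Paths are resolved relative to ``base_dir`` when given.
    """
    geom = VoxelGeometry(**manifest["geometry"])
    base = Path(base_dir) if base_dir is not None else Path(".")
    frames: list[tuple[float, dict[str, ImageStack]]] = []
    for fr in manifest["frames"]:
        chans = {name: read_stack(base / p, geom, channel=name)
                 for name, p in fr["channels"].items()}
        frames.append((float(fr["time"]), chans))
    return TimeLapse(frames, t0_index=int(manifest.get("t0_index", 0)))
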