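"""Substratum topography and surface-roughness metrology.

The substratum elevation field h(x, y) is recovered from the reflection
stack by scanning each (x, y) column from the top of the stack downward
and recording the first voxel whose intensity reaches a contrast
threshold.  Heights are reported as elevation above the deepest
detectable plane (larger = closer to the objective), so positive skewness
means hill-dominated and negative means valley-dominated terrain.

Roughness follows areal surface-texture metrology over the evaluated
area S, as discrete sums over the defined columns:

    Sa  = (1/S) Σ |h − h̄|          (average roughness, µm)
    Sq  = sqrt((1/S) Σ (h − h̄)²)   (RMS roughness, µm)
    Ssk = (1/Sq³)(1/S) Σ (h − h̄)³  (skewness, dimensionless)

The same statistics are evaluated globally, per square tile at multiple
window scales (multiscale area selection, MAS — a roughness census of
every candidate binding site), and per colonized site (the rectangular
footprint beneath each colonizer found at t0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import binarize
from .stacks_io import ImageStack, RegionOfInterest, VoxelGeometry


@dataclass
class HeightMap:
    """2D substratum elevation field in µm.

    ``h[y, x]`` is elevation above the deepest detectable plane;
    ``defined_mask`` marks columns where a surface was detected.
    """

    h: np.ndarray
    defined_mask: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.h.shape != self.defined_mask.shape or self.h.ndim != 2:
            raise ValueError("h and defined_mask must be matching 2D arrays")

    def crop(self, roi: RegionOfInterest) -> "HeightMap":
        ys, xs = slice(*roi.y_range), slice(*roi.x_range)
        return HeightMap(self.h[ys, xs].copy(), self.defined_mask[ys, xs].copy(),
                         self.geometry)


@dataclass(frozen=True)
class RoughnessStats:
    Sa: float                 # µm
    Sq: float                 # µm
    Ssk: float | None         # dimensionless; None when Sq == 0
    n_columns: int
    mean_height: float        # µm


def extract_heightmap(reflection_stack: ImageStack,
                      contrast_threshold: float | None = None) -> HeightMap:
    """Recover the substratum heightmap from a reflection stack.

    Scans every (x, y) column along Z from the top of the stack downward
    and takes the first voxel whose intensity reaches
    ``contrast_threshold`` (default: the stack's Otsu threshold) as the
    surface.  Columns with no hit are masked undefined.  A hit at Z index
    k (0 = top, Z slices total) gives elevation (Z − 1 − k)·dz.
    """
    values = np.asarray(reflection_stack.values)
    if reflection_stack.z_orientation == "bottom":
        values = values[::-1]
    if contrast_threshold is None:
        vmin, vmax = values.min(), values.max()
        if vmin == vmax:  # featureless stack: nothing detectable
            shape = values.shape[1:]
            return HeightMap(np.zeros(shape), np.zeros(shape, dtype=bool),
                             reflection_stack.geometry)
        contrast_threshold = binarize(reflection_stack, "otsu").threshold
        hit = values > contrast_threshold
    else:
        if not values.min() <= contrast_threshold <= values.max():
            raise ValueError(
                f"contrast_threshold {contrast_threshold} outside intensity "
                f"range [{values.min()}, {values.max()}]")
        hit = values >= contrast_threshold
    nz = values.shape[0]
    defined = hit.any(axis=0)
    first_hit = hit.argmax(axis=0)          # 0 for all-false columns; masked below
    h = (nz - 1 - first_hit) * reflection_stack.geometry.dz
    h[~defined] = np.nan
    return HeightMap(h, defined, reflection_stack.geometry)


def roughness(heightmap: HeightMap, roi: RegionOfInterest | None = None) -> RoughnessStats:
    """Sa / Sq / Ssk over the defined columns of a heightmap (or of an ROI)."""
    hm = heightmap.crop(roi) if roi is not None else heightmap
    h = hm.h[hm.defined_mask]
    if h.size < 2:
        raise ValueError("roughness requires at least 2 defined columns")
    dev = h - h.mean()
    sa = float(np.abs(dev).mean())
    sq = float(np.sqrt((dev ** 2).mean()))
    ssk = float((dev ** 3).mean() / sq ** 3) if sq > 0 else None
    return RoughnessStats(Sa=sa, Sq=sq, Ssk=ssk, n_columns=int(h.size),
                          mean_height=float(h.mean()))


def mas_scan(heightmap: HeightMap, window_areas: Sequence[float]) -> pd.DataFrame:
    """Multiscale area selection: tile the map and compute per-tile roughness.

    ``window_areas`` are square-window areas in µm²; each is converted to
    the nearest integer pixel side.  Tiling is non-overlapping, anchored
    at the map origin, with partial edge tiles dropped.  Tiles with fewer
    than 2 defined columns are skipped.

    Returns a DataFrame with columns
    ``tile_id, delta_l_um, x0, y0, side_px, Sa, Sq, Ssk, n_columns``.
    """
    if len(window_areas) == 0:
        raise ValueError("window_areas must be non-empty")
    ny, nx = heightmap.h.shape
    dx = heightmap.geometry.dx
    rows = []
    tile_id = 0
    for area in window_areas:
        side_px = max(1, round(np.sqrt(area) / dx))
        if side_px > min(nx, ny):
            raise ValueError(f"window side {side_px} px exceeds map extent {(ny, nx)}")
        for y0 in range(0, ny - side_px + 1, side_px):
            for x0 in range(0, nx - side_px + 1, side_px):
                roi = RegionOfInterest((x0, x0 + side_px), (y0, y0 + side_px))
                sub = heightmap.crop(roi)
                if sub.defined_mask.sum() < 2:
                    continue
                st = roughness(sub)
                rows.append(dict(tile_id=tile_id, delta_l_um=side_px * dx,
                                 x0=x0, y0=y0, side_px=side_px,
                                 Sa=st.Sa, Sq=st.Sq, Ssk=st.Ssk,
                                 n_columns=st.n_columns))
                tile_id += 1
    return pd.DataFrame(rows, columns=["tile_id", "delta_l_um", "x0", "y0",
                                       "side_px", "Sa", "Sq", "Ssk", "n_columns"])


def site_roughness(heightmap: HeightMap, elements_at_t0) -> pd.DataFrame:
    """Roughness of each colonized site.

    A site is the axis-aligned bounding rectangle of a colonizer's
    Z-projected footprint (elements from :mod:`biofilm4d.segmentation`,
    which carry pixel bounding boxes).  Returns a DataFrame with columns
    ``element_id, Sa, Sq, Ssk, n_columns``.
    """
    rows = []
    for el in elements_at_t0:
        (_, _), (y0, y1), (x0, x1) = el.bbox
        roi = RegionOfInterest((x0, x1), (y0, y1))
        sub = heightmap.crop(roi)
        if sub.defined_mask.sum() < 2:
            raise ValueError(f"element {el.id} footprint lies over undefined columns")
        st = roughness(sub)
        rows.append(dict(element_id=el.id, Sa=st.Sa, Sq=st.Sq, Ssk=st.Ssk,
                         n_columns=st.n_columns))
    return pd.DataFrame(rows, columns=["element_id", "Sa", "Sq", "Ssk", "n_columns"])


def occupancy_histograms(site_stats: pd.DataFrame, mas_stats: pd.DataFrame,
                         bin_spec: int | Sequence[float] = 30) -> dict[str, dict]:
    """Density-normalized histograms of Sa/Sq/Ssk: colonized vs non-colonized.

    For each metric the two tables are binned on shared edges spanning
    their joint range; each histogram integrates to 1.  Returns
    ``{metric: {"bins": edges, "occupied": density, "nca": density}}``.
    """
    if site_stats.empty or mas_stats.empty:
        raise ValueError("both site and MAS tables must be non-empty")
    out: dict[str, dict] = {}
    for metric in ("Sa", "Sq", "Ssk"):
        occ = site_stats[metric].dropna().to_numpy(dtype=float)
        nca = mas_stats[metric].dropna().to_numpy(dtype=float)
        joint = np.concatenate([occ, nca])
        if np.isscalar(bin_spec) and np.ndim(bin_spec) == 0:
            lo, hi = joint.min(), joint.max()
            if lo == hi:
                hi = lo + 1e-12
            edges = np.linspace(lo, hi, int(bin_spec) + 1)
        else:
            edges = np.asarray(bin_spec, dtype=float)
            if edges.size < 2 or np.any(np.diff(edges) <= 0):
                raise ValueError("degenerate bin spec")
        d_occ, _ = np.histogram(occ, bins=edges, density=True)
        d_nca, _ = np.histogram(nca, bins=edges, density=True)
        out[metric] = {"bins": edges, "occupied": d_occ, "nca": d_nca}
    return out
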