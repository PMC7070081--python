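"""3D labeling, volumetry and morphometrics of population units.

Each connected component of a binarized stack is one population unit
(an *element*): a single cell, a chain/cluster, an aggregate, or a
microcolony.  Volume is voxel count × voxel volume; cell counts are
estimated from biovolume using a reference single-cell volume of
0.35 µm³; morphology is summarized by the solidity ratio
qhull_volume / volume (≈1 for compact blob-like communities, large for
branched or filamentous ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .stacks_io import ImageStack, VoxelGeometry

#: Reference S. mutans single-cell biovolume, µm³.
UNIT_CELL_VOLUME = 0.35

#: Cell-count class bins: (lower exclusive is implied by the previous upper).
CLASS_BINS = (("single_cell", 5), ("cluster", 50), ("aggregate", 300))

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Element:
    """One segmented population unit at one frame.

    ``voxels`` holds the component's voxel indices as (z, y, x) arrays;
    ``bbox`` is half-open ((z0, z1), (y0, y1), (x0, x1)); ``centroid`` is
    in physical µm, ordered (x, y, z).  Hull-derived fields are ``None``
    until measured (or when the hull is degenerate).
    """

    id: int
    frame_time: float
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    volume: float
    centroid: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    qhull_volume: float | None = None
    solidity_ratio: float | None = None
    est_cells: int | None = None
    colonizer_class: str | None = None
    edge_flag: bool = False

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])


def label3d(binary_stack: ImageStack, connectivity: int = 26) -> list[Element]:
    """Label maximal 3D connected components of a binary stack.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full
    neighborhood; default — corner-touching cell chains are biologically
    contiguous).  Element ids are assigned in lexicographic order of each
    component's minimum (z, y, x) voxel, so labeling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(binary_stack.values).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    geom = binary_stack.geometry
    zz, yy, xx = np.nonzero(labels)
    labs = labels[zz, yy, xx]
    order = np.argsort(labs, kind="stable")  # raster order kept within a label
    zz, yy, xx, labs = zz[order], yy[order], xx[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, n + 2))
    comps = [(zz[bounds[i]:bounds[i + 1]], yy[bounds[i]:bounds[i + 1]],
              xx[bounds[i]:bounds[i + 1]]) for i in range(n)]
    # scipy assigns labels in raster-scan order of first voxel, which is the
    # lexicographic minimum already; sort explicitly so the order is a contract.
    comps.sort(key=lambda v: (v[0][0], v[1][0], v[2][0]))
    elements = []
    for i, (zz, yy, xx) in enumerate(comps):
        vol = len(zz) * geom.voxel_volume
        centroid = (float(xx.mean()) * geom.dx, float(yy.mean()) * geom.dy,
                    float(zz.mean()) * geom.dz)
        bbox = ((int(zz.min()), int(zz.max()) + 1),
                (int(yy.min()), int(yy.max()) + 1),
                (int(xx.min()), int(xx.max()) + 1))
        elements.append(Element(id=i, frame_time=0.0, voxels=(zz, yy, xx),
                                volume=vol, centroid=centroid, bbox=bbox))
    return elements


def filter_edge_elements(elements: list[Element],
                         stack_extent: tuple[int, int, int],
                         policy: str = "lateral") -> list[Element]:
    """Drop elements clipped by the field of view.

    Default policy ``"lateral"`` removes components touching an XY
    boundary (their volume and hull are corrupted by clipping) while
    keeping those that reach the top/bottom Z planes — biofilms
    legitimately fill the imaged depth.  ``"none"`` keeps everything but
    still sets ``edge_flag``.
    """
    if policy not in ("lateral", "none"):
        raise ValueError(f"unknown edge policy {policy!r}")
    nz, ny, nx = stack_extent
    kept = []
    for el in elements:
        (_, _), (y0, y1), (x0, x1) = el.bbox
        touches = x0 == 0 or y0 == 0 or x1 == nx or y1 == ny
        el.edge_flag = touches
        if policy == "none" or not touches:
            kept.append(el)
    return kept


def measure_volume(element: Element, geometry: VoxelGeometry) -> float:
    """Biovolume in µm³: voxel count × dx·dy·dz."""
    return element.n_voxels * geometry.voxel_volume


def _boundary_points(element: Element, geometry: VoxelGeometry) -> np.ndarray:
    """Physical positions (µm) of the element's boundary voxel centers."""
    (z0, z1), (y0, y1), (x0, x1) = element.bbox
    local = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=bool)
    zz, yy, xx = element.voxels
    local[zz - z0, yy - y0, xx - x0] = True
    interior = ndimage.binary_erosion(local, structure=_STRUCTURES[6],
                                      border_value=0)
    bz, by, bx = np.nonzero(local & ~interior)
    return np.column_stack([(bx + x0) * geometry.dx,
                            (by + y0) * geometry.dy,
                            (bz + z0) * geometry.dz]).astype(float)


def convex_hull_volume(element: Element, geometry: VoxelGeometry) -> float | None:
    """Volume (µm³) of the convex hull of the element's boundary voxel centers.

    The hull vertex convention is voxel *centers* (not ±half-voxel faces),
    so a solid a×b×c-voxel cuboid yields (a−1)(b−1)(c−1) voxel volumes.
    Degenerate elements (coplanar/collinear, < 4 points) return ``None``
    and leave solidity flagged undefined.
    """
    points = _boundary_points(element, geometry)
    if len(points) < 4:
        element.qhull_volume = None
        return None
    try:
        hull = ConvexHull(points)
    except QhullError:
        element.qhull_volume = None
        return None
    element.qhull_volume = float(hull.volume)
    return element.qhull_volume


def solidity(element: Element) -> float:
    """Solidity ratio qhull_volume / volume (hull must be measured first)."""
    if element.qhull_volume is None:
        raise ValueError(f"element {element.id}: hull undefined, solidity flagged")
    element.solidity_ratio = element.qhull_volume / element.volume
    return element.solidity_ratio


def estimate_cells(volume_um3: float, unit_cell_volume: float = UNIT_CELL_VOLUME) -> int:
    """Estimated cell count from biovolume (round half-up, floored at 1)."""
    if not volume_um3 > 0:
        raise ValueError("volume must be strictly positive")
    return max(1, math.floor(volume_um3 / unit_cell_volume + 0.5))


def classify_colonizer(est_cells: int) -> str:
    """Population-unit class from estimated cell count.

    single_cell: 1 ≤ P ≤ 5;  cluster: 5 < P ≤ 50;
    aggregate: 50 < P ≤ 300;  microcolony: P > 300.
    """
    if est_cells < 1:
        raise ValueError("est_cells must be ≥ 1")
    for name, upper in CLASS_BINS:
        if est_cells <= upper:
            return name
    return "microcolony"


def measure_elements(elements: list[Element], geometry: VoxelGeometry,
                     frame_time: float = 0.0,
                     unit_cell_volume: float = UNIT_CELL_VOLUME) -> list[Element]:
    """Fill hull, solidity, cell count and class on labeled elements."""
    for el in elements:
        el.frame_time = frame_time
        convex_hull_volume(el, geometry)
        if el.qhull_volume is not None:
            solidity(el)
        el.est_cells = estimate_cells(el.volume, unit_cell_volume)
        el.colonizer_class = classify_colonizer(el.est_cells)
    return elements


def surface_coverage(binary: ImageStack | np.ndarray,
                     geometry: VoxelGeometry | None = None) -> tuple[float, float]:
    """Occupied substratum area from the Z-projected foreground footprint.

    Accepts a binary stack (projected along Z) or an already projected 2D
    mask.  Returns ``(area_um2, fraction_of_field)``.
    """
    if isinstance(binary, ImageStack):
        geometry = binary.geometry
        footprint = np.asarray(binary.values).astype(bool).any(axis=0)
    else:
        if geometry is None:
            raise ValueError("geometry required for a bare projection array")
        footprint = np.asarray(binary).astype(bool)
        if footprint.ndim == 3:
            footprint = footprint.any(axis=0)
    count = int(footprint.sum())
    area = count * geometry.dx * geometry.dy
    return area, count / footprint.size
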