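"""3D labeling, volumetry, convex-hull morphometrics and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilm4d import (VoxelGeometry, classify_colonizer, convex_hull_volume,
                       estimate_cells, filter_edge_elements, label3d,
                       measure_volume, solidity, surface_coverage)

from conftest import element_from_mask, element_from_voxels, make_stack


def floodfill_oracle(mask, connectivity):
    """Brute-force BFS labeling; returns sorted component voxel-count list."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    visited = np.zeros_like(mask)
    sizes = []
    nz, ny, nx = mask.shape
    for z0, y0, x0 in zip(*np.nonzero(mask)):
        if visited[z0, y0, x0]:
            continue
        stack, size = [(z0, y0, x0)], 0
        visited[z0, y0, x0] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offs:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx \
                        and mask[zz, yy, xx] and not visited[zz, yy, xx]:
                    visited[zz, yy, xx] = True
                    stack.append((zz, yy, xx))
        sizes.append(size)
    return sorted(sizes)


class TestLabel3D:
    def test_two_separated_cubes(self, unit_geometry):
        v = np.zeros((10, 10, 10), dtype=np.uint8)
        v[1:4, 1:4, 1:4] = 1
        v[6:9, 6:9, 6:9] = 1
        els = label3d(make_stack(v, unit_geometry))
        assert len(els) == 2
        assert [el.n_voxels for el in els] == [27, 27]

    def test_corner_touch_depends_on_connectivity(self, unit_geometry):
        v = np.zeros((4, 4, 4), dtype=np.uint8)
        v[1, 1, 1] = 1
        v[2, 2, 2] = 1
        stack = make_stack(v, unit_geometry)
        assert len(label3d(stack, connectivity=26)) == 1
        assert len(label3d(stack, connectivity=6)) == 2

    def test_empty_stack_gives_no_elements(self, unit_geometry):
        assert label3d(make_stack(np.zeros((4, 4, 4), dtype=np.uint8),
                                  unit_geometry)) == []

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_floodfill_oracle(self, unit_geometry, rng, connectivity):
        for _ in range(5):
            mask = rng.random((16, 16, 16)) < 0.25
            els = label3d(make_stack(mask.astype(np.uint8), unit_geometry),
                          connectivity=connectivity)
            assert sorted(el.n_voxels for el in els) == \
                floodfill_oracle(mask, connectivity)

    def test_volume_conservation_before_edge_filter(self, geometry, rng):
        mask = rng.random((12, 12, 12)) < 0.2
        els = label3d(make_stack(mask.astype(np.uint8), geometry))
        total = sum(el.volume for el in els)
        assert total == pytest.approx(mask.sum() * geometry.voxel_volume)

    def test_translation_invariance_up_to_relabeling(self, unit_geometry, rng):
        mask = np.zeros((20, 20, 20), dtype=np.uint8)
        mask[2:6, 2:6, 2:6] = 1
        mask[10:12, 3:8, 4:5] = 1
        shifted = np.roll(mask, (3, 4, 5), axis=(0, 1, 2))
        a = label3d(make_stack(mask, unit_geometry))
        b = label3d(make_stack(shifted, unit_geometry))
        assert sorted(el.n_voxels for el in a) == sorted(el.n_voxels for el in b)

    def test_deterministic_id_order(self, unit_geometry):
        v = np.zeros((6, 6, 6), dtype=np.uint8)
        v[4, 4, 4] = 1   # later in raster order
        v[1, 1, 1] = 1
        els = label3d(make_stack(v, unit_geometry))
        assert [el.voxels[0][0] for el in els] == [1, 4]


class TestEdgeFilter:
    def test_interior_element_retained(self, unit_geometry):
        v = np.zeros((8, 8, 8), dtype=np.uint8)
        v[2:5, 2:5, 2:5] = 1
        els = label3d(make_stack(v, unit_geometry))
        kept = filter_edge_elements(els, v.shape)
        assert len(kept) == 1 and not kept[0].edge_flag

    def test_laterally_clipped_element_removed(self, unit_geometry):
        v = np.zeros((8, 8, 8), dtype=np.uint8)
        v[3:5, 3:5, 0:3] = 1  # touches x = 0 plane
        els = label3d(make_stack(v, unit_geometry))
        assert filter_edge_elements(els, v.shape) == []

    def test_z_touching_element_retained(self, unit_geometry):
        v = np.zeros((8, 8, 8), dtype=np.uint8)
        v[0:3, 3:5, 3:5] = 1  # touches top Z plane only
        els = label3d(make_stack(v, unit_geometry))
        assert len(filter_edge_elements(els, v.shape)) == 1

    def test_random_scene_matches_index_bound_oracle(self, unit_geometry, rng):
        mask = rng.random((14, 14, 14)) < 0.15
        els = label3d(make_stack(mask.astype(np.uint8), unit_geometry))
        kept = filter_edge_elements(list(els), mask.shape)
        kept_ids = {el.id for el in kept}
        for el in els:
            zz, yy, xx = el.voxels
            touches = (xx.min() == 0 or yy.min() == 0
                       or xx.max() == 13 or yy.max() == 13)
            assert (el.id in kept_ids) == (not touches)


class TestVolumeAndHull:
    def test_volume_is_count_times_voxel_volume(self):
        g = VoxelGeometry(0.1, 0.1, 0.42)
        zz = np.zeros(100, dtype=int)
        el = element_from_voxels(zz, np.arange(100) // 10, np.arange(100) % 10)
        assert measure_volume(el, g) == pytest.approx(0.42)

    def test_single_voxel_volume(self, geometry):
        el = element_from_voxels([2], [3], [4])
        assert measure_volume(el, geometry) == pytest.approx(geometry.voxel_volume)

    def test_digitized_sphere_volume_near_analytic(self, unit_geometry):
        r = 5
        zz, yy, xx = np.mgrid[:13, :13, :13]
        mask = (zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= r * r
        el = element_from_mask(mask)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        assert measure_volume(el, unit_geometry) == pytest.approx(analytic, rel=0.05)

    def test_cuboid_hull_volume(self, unit_geometry):
        a, b, c = 5, 6, 7
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:1 + a, 1:1 + b, 1:1 + c] = True
        el = element_from_mask(mask)
        hv = convex_hull_volume(el, unit_geometry)
        assert hv == pytest.approx((a - 1) * (b - 1) * (c - 1))

    def test_tetrahedron_hull_is_det_over_six(self, unit_geometry):
        zz, yy, xx = [0, 5, 0, 0], [0, 0, 7, 0], [0, 0, 0, 6]
        el = element_from_voxels(zz, yy, xx)
        hv = convex_hull_volume(el, unit_geometry)
        edges = np.array([[0, 0, 5.0], [0, 7, 0], [6, 0, 0]])  # (x, y, z) rows
        assert hv == pytest.approx(abs(np.linalg.det(edges)) / 6, abs=1e-9)

    def test_hull_depends_on_surface_only(self, unit_geometry):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[1:8, 1:8, 1:8] = True
        solid = element_from_mask(mask)
        hollow_mask = mask.copy()
        hollow_mask[2:7, 2:7, 2:7] = False
        hollow = element_from_mask(hollow_mask)
        assert convex_hull_volume(solid, unit_geometry) == \
            pytest.approx(convex_hull_volume(hollow, unit_geometry))

    def test_coplanar_element_hull_flagged(self, unit_geometry):
        el = element_from_voxels([1, 1, 1, 1], [0, 0, 3, 3], [0, 3, 0, 3])
        assert convex_hull_volume(el, unit_geometry) is None
        with pytest.raises(ValueError):
            solidity(el)


class TestSolidity:
    def test_solid_cuboid_near_one(self, unit_geometry):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[1:13, 1:13, 1:13] = True
        el = element_from_mask(mask)
        convex_hull_volume(el, unit_geometry)
        assert solidity(el) == pytest.approx(1.0, abs=0.3)

    def test_thin_cross_exceeds_two(self, unit_geometry):
        mask = np.zeros((5, 31, 31), dtype=bool)
        mask[1:4, 15:16, 2:29] = True   # bar along x, 1 px wide
        mask[1:4, 2:29, 15:16] = True   # bar along y
        el = element_from_mask(mask)
        convex_hull_volume(el, unit_geometry)
        assert solidity(el) > 2.0

    def test_sphere_solidity_approaches_one_with_resolution(self, unit_geometry):
        vals = []
        for r in (8, 16):
            n = 2 * r + 3
            zz, yy, xx = np.mgrid[:n, :n, :n]
            c = n // 2
            mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r * r
            el = element_from_mask(mask)
            convex_hull_volume(el, unit_geometry)
            vals.append(solidity(el))
        assert abs(vals[1] - 1.0) < abs(vals[0] - 1.0)


class TestCellCountAndClass:
    @pytest.mark.parametrize("volume, expected", [
        (0.35, 1), (1.75, 5), (0.01, 1), (0.35 * 6.4, 6),
    ])
    def test_cell_count_examples(self, volume, expected):
        assert estimate_cells(volume) == expected

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_cells(0.0)

    @given(v1=st.floats(0.01, 500), v2=st.floats(0.01, 500))
    @settings(max_examples=50, deadline=None)
    def test_cell_count_monotone_in_volume(self, v1, v2):
        lo, hi = sorted((v1, v2))
        assert estimate_cells(lo) <= estimate_cells(hi)

    @pytest.mark.parametrize("cells, expected", [
        (1, "single_cell"), (5, "single_cell"), (6, "cluster"),
        (50, "cluster"), (51, "aggregate"), (300, "aggregate"),
        (301, "microcolony"),
    ])
    def test_class_bin_edges(self, cells, expected):
        assert classify_colonizer(cells) == expected


class TestSurfaceCoverage:
    def test_full_field_slab(self, geometry):
        v = np.zeros((5, 10, 10), dtype=np.uint8)
        v[2] = 1
        area, frac = surface_coverage(make_stack(v, geometry))
        assert frac == 1.0

    def test_area_arithmetic(self):
        g = VoxelGeometry(0.1, 0.1, 0.42)
        v = np.zeros((3, 20, 20), dtype=np.uint8)
        v[1, 5:15, 5:15] = 1
        area, frac = surface_coverage(make_stack(v, g))
        assert area == pytest.approx(1.0)
        assert frac == pytest.approx(100 / 400)

    def test_matches_projection_counting_oracle(self, geometry, rng):
        mask = rng.random((6, 12, 12)) < 0.1
        area, frac = surface_coverage(make_stack(mask.astype(np.uint8), geometry))
        count = sum(1 for y in range(12) for x in range(12)
                    if any(mask[z, y, x] for z in range(6)))
        assert area == pytest.approx(count * geometry.dx * geometry.dy)
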