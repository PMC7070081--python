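"""Heightmap extraction, roughness statistics, MAS and site analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilm4d import (HeightMap, RegionOfInterest, extract_heightmap,
                       mas_scan, occupancy_histograms, roughness,
                       site_roughness)

from conftest import element_from_mask, make_stack


def roughness_oracle(h):
    """Direct per-column summation of the Sa/Sq/Ssk definitions."""
    h = [float(v) for v in np.asarray(h).ravel() if np.isfinite(v)]
    n = len(h)
    hbar = sum(h) / n
    sa = sum(abs(v - hbar) for v in h) / n
    sq = (sum((v - hbar) ** 2 for v in h) / n) ** 0.5
    ssk = (sum((v - hbar) ** 3 for v in h) / n) / sq ** 3 if sq > 0 else None
    return sa, sq, ssk


def heightmap_from(h, geometry):
    h = np.asarray(h, dtype=float)
    return HeightMap(h, np.isfinite(h), geometry)


class TestExtractHeightmap:
    def test_solid_slab_gives_constant_defined_heightmap(self, geometry):
        v = np.full((10, 8, 8), 10, dtype=np.uint8)
        v[6:] = 200  # surface fills all z >= 6 (top-down index)
        hm = extract_heightmap(make_stack(v, geometry, channel="reflection"),
                               contrast_threshold=100)
        assert hm.defined_mask.all()
        np.testing.assert_allclose(hm.h, (10 - 1 - 6) * geometry.dz)

    def test_two_level_step_matches_per_column_scan_oracle(self, geometry):
        nz, ny, nx = 12, 6, 8
        v = np.full((nz, ny, nx), 5, dtype=np.uint8)
        k1, k2 = 3, 9
        v[k1:, :, :nx // 2] = 220
        v[k2:, :, nx // 2:] = 220
        hm = extract_heightmap(make_stack(v, geometry, channel="reflection"),
                               contrast_threshold=100)
        for y in range(ny):
            for x in range(nx):
                first = next(z for z in range(nz) if v[z, y, x] >= 100)
                assert hm.h[y, x] == pytest.approx((nz - 1 - first) * geometry.dz)

    def test_featureless_stack_fully_undefined(self, geometry):
        v = np.full((6, 5, 5), 3, dtype=np.uint8)
        hm = extract_heightmap(make_stack(v, geometry, channel="reflection"))
        assert not hm.defined_mask.any()

    def test_threshold_outside_range_rejected(self, geometry):
        v = np.full((6, 5, 5), 3, dtype=np.uint8)
        with pytest.raises(ValueError):
            extract_heightmap(make_stack(v, geometry, channel="reflection"),
                              contrast_threshold=250)


class TestRoughness:
    def test_flat_map_has_zero_roughness_and_undefined_skew(self, geometry):
        st_ = roughness(heightmap_from(np.full((8, 8), 3.0), geometry))
        assert st_.Sa == 0 and st_.Sq == 0 and st_.Ssk is None

    def test_two_level_map_matches_hand_computation(self, geometry):
        h = np.zeros((4, 8))
        h[:, 4:] = 2.0
        st_ = roughness(heightmap_from(h, geometry))
        assert st_.Sa == pytest.approx(1.0)
        assert st_.Sq == pytest.approx(1.0)
        assert st_.Ssk == pytest.approx(0.0)

    def test_spike_positive_pit_negative_skewness(self, geometry):
        h = np.zeros((5, 5))
        h[2, 2] = 4.0
        assert roughness(heightmap_from(h, geometry)).Ssk > 0
        assert roughness(heightmap_from(-h, geometry)).Ssk < 0

    def test_matches_direct_summation_oracle(self, geometry, rng):
        for _ in range(10):
            h = rng.normal(2.0, 0.7, size=(16, 16))
            st_ = roughness(heightmap_from(h, geometry))
            sa, sq, ssk = roughness_oracle(h)
            assert st_.Sa == pytest.approx(sa, abs=1e-9)
            assert st_.Sq == pytest.approx(sq, abs=1e-9)
            assert st_.Ssk == pytest.approx(ssk, abs=1e-9)

    def test_undefined_columns_excluded(self, geometry):
        h = np.full((4, 4), 1.0)
        h[0, 0] = np.nan
        h[1:, :] = 2.0
        st_ = roughness(heightmap_from(h, geometry))
        assert st_.n_columns == 15
        sa, sq, _ = roughness_oracle(h)
        assert st_.Sa == pytest.approx(sa)

    @given(offset=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_constant_offset(self, offset):
        from biofilm4d import VoxelGeometry
        h = np.random.default_rng(3).normal(0, 1, size=(12, 12))
        g = VoxelGeometry(0.5, 0.5, 0.42)
        a = roughness(heightmap_from(h, g))
        b = roughness(heightmap_from(h + offset, g))
        assert b.Sa == pytest.approx(a.Sa, rel=1e-9, abs=1e-9)
        assert b.Sq == pytest.approx(a.Sq, rel=1e-9, abs=1e-9)
        assert b.Ssk == pytest.approx(a.Ssk, rel=1e-7, abs=1e-7)

    def test_negation_flips_skew_only(self, geometry, rng):
        h = rng.normal(0, 1, size=(10, 10)) ** 3
        a = roughness(heightmap_from(h, geometry))
        b = roughness(heightmap_from(-h, geometry))
        assert b.Sa == pytest.approx(a.Sa)
        assert b.Sq == pytest.approx(a.Sq)
        assert b.Ssk == pytest.approx(-a.Ssk)


class TestMasScan:
    def test_constant_map_all_tiles_flat(self, geometry):
        hm = heightmap_from(np.full((40, 40), 2.0), geometry)
        table = mas_scan(hm, [25.0])  # 10 px windows at dx=0.5
        assert (table["Sa"] == 0).all()

    def test_full_map_window_reproduces_global(self, geometry, rng):
        h = rng.normal(1, 0.5, size=(20, 20))
        hm = heightmap_from(h, geometry)
        side_um = 20 * geometry.dx
        table = mas_scan(hm, [side_um ** 2])
        assert len(table) == 1
        glob = roughness(hm)
        assert table.loc[0, "Sa"] == pytest.approx(glob.Sa)
        assert table.loc[0, "Sq"] == pytest.approx(glob.Sq)
        assert table.loc[0, "Ssk"] == pytest.approx(glob.Ssk)

    def test_tile_count_is_floor_division(self, geometry, rng):
        h = rng.normal(0, 1, size=(100, 100))
        table = mas_scan(heightmap_from(h, geometry), [(10 * geometry.dx) ** 2])
        assert len(table) == 100

    def test_empty_window_list_rejected(self, geometry):
        with pytest.raises(ValueError):
            mas_scan(heightmap_from(np.zeros((10, 10)), geometry), [])


class TestSiteRoughness:
    def test_site_over_flat_region_is_smooth(self, geometry):
        hm = heightmap_from(np.full((20, 20), 1.5), geometry)
        footprint = np.zeros((3, 20, 20), dtype=bool)
        footprint[1, 5:9, 5:9] = True
        el = element_from_mask(footprint)
        table = site_roughness(hm, [el])
        assert table.loc[0, "Sa"] == 0

    def test_equals_crop_then_compute_oracle(self, geometry, rng):
        h = rng.normal(2, 0.8, size=(30, 30))
        hm = heightmap_from(h, geometry)
        elements = []
        for i in range(5):
            x0, y0 = rng.integers(0, 20, size=2)
            m = np.zeros((2, 30, 30), dtype=bool)
            m[0, y0:y0 + 8, x0:x0 + 8] = True
            elements.append(element_from_mask(m, element_id=i))
        table = site_roughness(hm, elements)
        for i, el in enumerate(elements):
            (_, _), (y0, y1), (x0, x1) = el.bbox
            ref = roughness(hm.crop(RegionOfInterest((x0, x1), (y0, y1))))
            assert table.loc[i, "Sa"] == pytest.approx(ref.Sa)
            assert table.loc[i, "Ssk"] == pytest.approx(ref.Ssk)


class TestOccupancyHistograms:
    def _table(self, rng, n):
        return pd.DataFrame({"Sa": rng.random(n), "Sq": rng.random(n) + 1,
                             "Ssk": rng.normal(0, 1, n)})

    def test_identical_tables_give_identical_histograms(self, rng):
        t = self._table(rng, 50)
        out = occupancy_histograms(t, t.copy())
        for metric in ("Sa", "Sq", "Ssk"):
            np.testing.assert_allclose(out[metric]["occupied"],
                                       out[metric]["nca"])

    def test_histograms_integrate_to_one(self, rng):
        out = occupancy_histograms(self._table(rng, 40), self._table(rng, 80))
        for metric in ("Sa", "Sq", "Ssk"):
            h = out[metric]
            widths = np.diff(h["bins"])
            assert abs((h["occupied"] * widths).sum() - 1.0) < 1e-9
            assert abs((h["nca"] * widths).sum() - 1.0) < 1e-9

    def test_degenerate_bins_rejected(self, rng):
        t = self._table(rng, 10)
        with pytest.raises(ValueError):
            occupancy_histograms(t, t, bin_spec=[1.0, 1.0])

    def test_sites_sampled_from_tiles_overlap_strongly(self, rng):
        """Sites drawn from the MAS population produce near-identical densities."""
        mas = self._table(rng, 400)
        sites = mas.sample(n=200, random_state=5)
        out = occupancy_histograms(sites, mas, bin_spec=8)
        for metric in ("Sa", "Sq", "Ssk"):
            h = out[metric]
            widths = np.diff(h["bins"])
            overlap = (np.minimum(h["occupied"], h["nca"]) * widths).sum()
            assert overlap > 0.8
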