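"""Spherical cell areas and zonal (per-region) area accounting."""

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import Point, box

from ecorange import GridLayer, GridTransform, RegionSet, cell_area, clip_mask, summarize_by_region
from ecorange.regions import EARTH_RADIUS_KM, UNASSIGNED, row_areas


def _global_one_degree_mask(true_cells=None):
    values = np.zeros((180, 360), dtype=np.uint8)
    if true_cells is not None:
        for r, c in true_cells:
            values[r, c] = 1
    t = GridTransform(west=-180.0, north=90.0, dx=1.0, dy=1.0)
    return GridLayer("mask", "bool", values, t, nodata=255)


class TestCellArea:
    def test_equator_cell_matches_numerical_integration(self):
        """1°×1° cell at the equator ≈ 12,364 km², via an independent
        numerical integration of R²·cosφ over the cell."""
        mask = _global_one_degree_mask()
        got = cell_area(89, mask)  # row 89 spans 0..1°N
        expected = EARTH_RADIUS_KM**2 * np.radians(1.0) * quad(
            lambda phi: np.cos(phi), 0.0, np.radians(1.0))[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(12364, rel=5e-4)

    def test_global_sum_is_sphere_surface(self):
        """Summing every 1° cell reproduces 4πR² to 1e-6 relative."""
        mask = _global_one_degree_mask()
        total = row_areas(mask).sum() * 360
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-6)

    def test_area_shrinks_toward_poles(self):
        mask = _global_one_degree_mask()
        assert cell_area(0, mask) < cell_area(89, mask)  # 89-90°N vs 0-1°N
        assert cell_area(45, mask) < cell_area(80, mask)

    def test_planar_approximation_below_60deg(self):
        """R²-zone area agrees with (111.195 km/deg)²·cosφ within 1% for |φ|≤60°."""
        mask = _global_one_degree_mask()
        for row in range(30, 150):  # centers between ±59.5°
            lat_c = 89.5 - row
            planar = 111.195**2 * np.cos(np.radians(lat_c))
            assert cell_area(row, mask) == pytest.approx(planar, rel=0.01)

    def test_row_out_of_range(self):
        with pytest.raises(IndexError):
            cell_area(180, _global_one_degree_mask())


class TestSummarize:
    def _regions(self):
        return RegionSet(regions=[("A", box(-180, 0, 0, 90)),
                                  ("B", box(0, 0, 180, 90)),
                                  ("C", box(-180, -90, 180, 0))])

    def test_all_area_in_one_region(self):
        mask = _global_one_degree_mask([(20, 30), (40, 50)])  # northern, west
        summary = summarize_by_region(mask, self._regions())
        assert summary.area_of("A") == pytest.approx(summary.total_area_km2)
        assert summary.area_of(UNASSIGNED) == 0.0

    def test_empty_mask(self):
        summary = summarize_by_region(_global_one_degree_mask(), self._regions())
        assert summary.total_area_km2 == 0.0
        assert summary.total_cells == 0

    def test_partition_additivity(self):
        """Disjoint covering regions: per-region areas sum to the mask total."""
        rng = np.random.default_rng(12)
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 180, 400), rng.integers(0, 360, 400))]
        mask = _global_one_degree_mask(cells)
        summary = summarize_by_region(mask, self._regions())
        parts = summary.table["area_km2"].sum()
        assert parts == pytest.approx(summary.total_area_km2, rel=1e-9)
        assert summary.area_of(UNASSIGNED) == 0.0

    def test_unassigned_cells_reported(self):
        mask = _global_one_degree_mask([(100, 10)])  # southern hemisphere
        regions = RegionSet(regions=[("north", box(-180, 0, 180, 90))])
        summary = summarize_by_region(mask, regions)
        assert summary.area_of(UNASSIGNED) == pytest.approx(summary.total_area_km2)

    def test_matches_point_in_polygon_oracle(self):
        """10×10 toy mask vs a scalar cell-by-cell point-in-polygon count."""
        values = np.zeros((10, 10), dtype=np.uint8)
        rng = np.random.default_rng(3)
        values[rng.random((10, 10)) < 0.4] = 1
        t = GridTransform(west=0.0, north=10.0, dx=1.0, dy=1.0)
        mask = GridLayer("m", "bool", values, t, nodata=255)
        regions = RegionSet(regions=[("L", box(0, 0, 4.5, 10)),
                                     ("R", box(4.5, 0, 10, 10))])
        summary = summarize_by_region(mask, regions)

        expected = {"L": 0.0, "R": 0.0, UNASSIGNED: 0.0}
        for r in range(10):
            for c in range(10):
                if not values[r, c]:
                    continue
                center = Point(c + 0.5, 10 - r - 0.5)
                area = cell_area(r, mask)
                if regions["L"].contains(center):
                    expected["L"] += area
                elif regions["R"].contains(center):
                    expected["R"] += area
                else:
                    expected[UNASSIGNED] += area
        for name, val in expected.items():
            assert summary.area_of(name) == pytest.approx(val, rel=1e-12)

    def test_rank_order_with_alphabetical_ties(self):
        mask = _global_one_degree_mask([(30, 10), (30, 200)])  # same row: equal area
        regions = RegionSet(regions=[("zeta", box(0, 0, 180, 90)),
                                     ("alpha", box(-180, 0, 0, 90))])
        summary = summarize_by_region(mask, regions)
        assert summary.table["region"].tolist()[:2] == ["alpha", "zeta"]

    def test_mask_monotonicity(self):
        base = _global_one_degree_mask([(10, 10)])
        more = _global_one_degree_mask([(10, 10), (11, 11)])
        regions = self._regions()
        a = summarize_by_region(base, regions)
        b = summarize_by_region(more, regions)
        for name in regions.names() + [UNASSIGNED]:
            assert b.area_of(name) >= a.area_of(name)


class TestClip:
    def test_clip_identity_and_empty(self):
        mask = _global_one_degree_mask([(20, 30), (120, 300)])
        regions = RegionSet(regions=[("all", box(-180, -90, 180, 90)),
                                     ("nowhere", box(200 - 360, -90, 210 - 360, -89.5))])
        full = clip_mask(mask, regions, "all")
        np.testing.assert_array_equal(full.values, mask.values)
        none = clip_mask(mask, regions, "nowhere")
        assert not none.values.astype(bool).any()

    def test_clip_area_equals_region_row(self):
        mask = _global_one_degree_mask([(20, 30), (40, 50), (120, 300)])
        regions = RegionSet(regions=[("A", box(-180, 0, 0, 90)),
                                     ("B", box(0, -90, 180, 90))])
        summary = summarize_by_region(mask, regions)
        clipped = clip_mask(mask, regions, "A")
        area = sum(cell_area(r, mask) for r, c in zip(*np.nonzero(clipped.values == 1)))
        assert area == pytest.approx(summary.area_of("A"), rel=1e-12)

    def test_unknown_region_errors(self):
        mask = _global_one_degree_mask()
        with pytest.raises(KeyError):
            clip_mask(mask, RegionSet(regions=[("A", box(0, 0, 1, 1))]), "Z")
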