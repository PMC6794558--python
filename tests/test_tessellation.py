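import math

import numpy as np
import pytest

from gazetess import build_voronoi, label_cells
from gazetess.tessellation import (
    BACKGROUND_LABEL,
    OFF_SCREEN_LABEL,
    assign_by_containment,
    assign_fixations,
)

from .test_clustering import _fixset


class TestBuildVoronoi:
    def test_two_sites_split_along_bisector(self, geometry):
        aoi = build_voronoi(np.array([[320.0, 512.0], [960.0, 512.0]]), geometry)
        assert len(aoi.cells) == 2
        for cell in aoi.cells:
            assert cell.area == pytest.approx(655_360.0)
        # boundary is the vertical line x = 640
        xs = [x for x, _ in aoi.cells[0].polygon.exterior.coords]
        assert max(xs) == pytest.approx(640.0)

    def test_single_site_owns_whole_screen(self, geometry):
        aoi = build_voronoi(np.array([[500.0, 500.0]]), geometry)
        assert len(aoi.cells) == 1
        assert aoi.cells[0].area == pytest.approx(1_310_720.0)

    def test_duplicate_sites_rejected(self, geometry):
        with pytest.raises(ValueError, match="degenerate sites"):
            build_voronoi(np.array([[100.0, 100.0], [100.0, 100.0]]), geometry)

    def test_off_screen_site_rejected(self, geometry):
        with pytest.raises(ValueError, match="outside the screen"):
            build_voronoi(np.array([[-5.0, 100.0]]), geometry)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_areas_sum_to_screen_area(self, geometry, seed):
        rng = np.random.default_rng(seed)
        sites = rng.uniform([5, 5], [1275, 1019], size=(10, 2))
        aoi = build_voronoi(sites, geometry)
        assert math.isclose(aoi.total_area(), geometry.screen_area_px, rel_tol=1e-9)

    def test_monte_carlo_area_agreement(self, geometry):
        rng = np.random.default_rng(3)
        sites = rng.uniform([50, 50], [1230, 974], size=(8, 2))
        aoi = build_voronoi(sites, geometry)
        n = 100_000
        xs = rng.uniform(0, geometry.raster_width, n)
        ys = rng.uniform(0, geometry.raster_height, n)
        d2 = (xs[:, None] - sites[None, :, 0]) ** 2 + (ys[:, None] - sites[None, :, 1]) ** 2
        counts = np.bincount(d2.argmin(axis=1), minlength=len(sites))
        mc_areas = counts / n * geometry.screen_area_px
        for cell, mc in zip(aoi.cells, mc_areas):
            assert abs(cell.area - mc) / geometry.screen_area_px < 0.005

    def test_sites_inside_own_cells_and_cells_convex(self, geometry):
        rng = np.random.default_rng(4)
        sites = rng.uniform([10, 10], [1270, 1014], size=(12, 2))
        aoi = build_voronoi(sites, geometry)
        from shapely.geometry import Point

        for cell in aoi.cells:
            assert cell.polygon.covers(Point(*cell.centroid))
            assert cell.polygon.convex_hull.area == pytest.approx(cell.area, rel=1e-9)


class TestLabelCells:
    def test_unnamed_cells_default_to_background(self, geometry):
        sites = np.array([[200.0, 200.0], [640.0, 512.0], [1100.0, 900.0]])
        aoi = label_cells(build_voronoi(sites, geometry), {0: "Face", 1: "Target"})
        assert aoi.labels == ["Face", "Target", BACKGROUND_LABEL]

    def test_empty_map_all_background(self, geometry):
        sites = np.array([[200.0, 200.0], [1000.0, 800.0]])
        aoi = label_cells(build_voronoi(sites, geometry), {})
        assert aoi.labels == [BACKGROUND_LABEL, BACKGROUND_LABEL]

    def test_unknown_index_errors(self, geometry):
        aoi = build_voronoi(np.array([[500.0, 500.0]]), geometry)
        with pytest.raises(KeyError, match="unknown cell index"):
            label_cells(aoi, {3: "Face"})

    def test_labeling_preserves_geometry(self, geometry):
        sites = np.array([[200.0, 200.0], [1000.0, 800.0]])
        before = build_voronoi(sites, geometry)
        after = label_cells(before, {0: "Face"})
        for a, b in zip(before.cells, after.cells):
            assert a.polygon.equals(b.polygon)
            assert a.centroid == b.centroid

    def test_shared_labels_allowed(self, geometry):
        sites = np.array([[200.0, 200.0], [1000.0, 800.0]])
        aoi = label_cells(build_voronoi(sites, geometry), {0: "Target", 1: "Target"})
        assert aoi.labels == ["Target", "Target"]


class TestAssignFixations:
    def test_nearest_site_assignment(self, geometry):
        aoi = label_cells(
            build_voronoi(np.array([[320.0, 512.0], [960.0, 512.0]]), geometry),
            {0: "Left", 1: "Right"},
        )
        fs = _fixset([(100.0, 100.0)], geometry)
        out = assign_fixations(fs, aoi)
        assert out.loc[0, "cell"] == 0
        assert out.loc[0, "aoi_label"] == "Left"

    def test_bisector_tie_breaks_to_lower_index(self, geometry):
        aoi = build_voronoi(np.array([[320.0, 512.0], [960.0, 512.0]]), geometry)
        fs = _fixset([(640.0, 512.0)], geometry)
        out = assign_fixations(fs, aoi)
        assert out.loc[0, "cell"] == 0

    def test_off_screen_fixations_labeled(self, geometry):
        aoi = build_voronoi(np.array([[640.0, 512.0]]), geometry)
        fs = _fixset([(640.0, 512.0), (-10.0, 50.0)], geometry)
        out = assign_fixations(fs, aoi)
        assert out.loc[1, "cell"] == -1
        assert out.loc[1, "aoi_label"] == OFF_SCREEN_LABEL

    def test_containment_equals_nearest_site(self, geometry):
        """Dual-route check on 10^4 random points (off the null-measure
        boundaries): polygon containment and nearest-centroid agree."""
        rng = np.random.default_rng(7)
        sites = rng.uniform([20, 20], [1260, 1004], size=(9, 2))
        aoi = build_voronoi(sites, geometry)
        xs = rng.uniform(0, geometry.raster_width, 10_000)
        ys = rng.uniform(0, geometry.raster_height, 10_000)
        by_contain = assign_by_containment(aoi, xs, ys)
        d2 = (xs[:, None] - sites[None, :, 0]) ** 2 + (ys[:, None] - sites[None, :, 1]) ** 2
        by_near = d2.argmin(axis=1)
        assert np.array_equal(by_contain, by_near)

    def test_uniform_points_fall_in_exactly_one_cell(self, geometry):
        rng = np.random.default_rng(8)
        sites = rng.uniform([20, 20], [1260, 1004], size=(6, 2))
        aoi = build_voronoi(sites, geometry)
        xs = rng.uniform(0, geometry.raster_width, 2000)
        ys = rng.uniform(0, geometry.raster_height, 2000)
        from shapely.geometry import Point

        hits = np.zeros(len(xs), dtype=int)
        for cell in aoi.cells:
            for k in range(len(xs)):
                if cell.polygon.contains(Point(xs[k], ys[k])):
                    hits[k] += 1
        # strict interior containment: every point in at least one closed cell
        # and never strictly inside two
        assert np.all(hits <= 1)
        covers = assign_by_containment(aoi, xs, ys)
        assert np.all(covers >= 0)
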