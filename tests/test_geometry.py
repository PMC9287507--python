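"""Geometry primitives against closed forms and hand geometry."""

import math

import numpy as np
import pytest
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon, box

from farmscape.geometry import (
    InvalidGeometryError,
    InvalidMosaicError,
    LandCoverPatch,
    ParameterError,
    buffer_region,
    mean_interior_distance,
    overlay_area,
    polygon_area,
    shared_border_length,
)


def patch(minx, miny, maxx, maxy, cls, pid="p"):
    return LandCoverPatch(box(minx, miny, maxx, maxy), cls, pid)


class TestPolygonArea:
    @pytest.mark.parametrize(
        "poly, expected",
        [
            (box(0, 0, 1, 1), 1.0),
            (Polygon(box(0, 0, 100, 100).exterior, [box(40, 40, 50, 50).exterior]), 9900.0),
            (Polygon([(0, 0), (4, 0), (0, 3)]), 6.0),  # shoelace by hand
        ],
    )
    def test_matches_closed_form(self, poly, expected):
        assert polygon_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_rigid_motion_invariance(self):
        poly = Polygon([(0, 0), (13, 2), (11, 9), (3, 7)])
        moved = rotate(translate(poly, 1234.5, -987.6), 37.3, origin=(4, 4))
        assert polygon_area(moved) == pytest.approx(polygon_area(poly), rel=1e-9)

    def test_degenerate_ring_rejected(self):
        with pytest.raises(InvalidGeometryError):
            polygon_area(Polygon([(0, 0), (1, 0), (2, 0)]))


class TestBufferRegion:
    def test_square_dilation_closed_form(self):
        # area = A + P*d + pi*d^2 for a convex polygon
        out = buffer_region([box(0, 0, 100, 100)], 50.0)
        expected = 10_000 + 4 * 100 * 50 + math.pi * 50**2
        assert out.area == pytest.approx(expected, rel=0.01)
        assert out.area < expected  # inscribed arc approximation

    def test_distant_squares_stay_disjoint(self):
        out = buffer_region([box(0, 0, 100, 100), box(1100, 0, 1200, 100)], 50.0)
        assert out.geom_type == "MultiPolygon" and len(out.geoms) == 2

    def test_abutting_squares_merge(self):
        out = buffer_region([box(0, 0, 100, 100), box(100, 0, 200, 100)], 50.0)
        assert out.geom_type == "Polygon"

    def test_monotone_in_distance_and_bounds_input(self):
        base = box(0, 0, 60, 40)
        prev = base.area
        for d in (10, 25, 50, 80):
            area = buffer_region([base], d).area
            assert area > prev
            prev = area

    def test_tolerance_controls_arc_error(self):
        circleish_coarse = buffer_region([box(0, 0, 10, 10)], 100.0, arc_tolerance=20.0)
        circleish_fine = buffer_region([box(0, 0, 10, 10)], 100.0, arc_tolerance=0.1)
        true = 100 + 4 * 10 * 100 + math.pi * 100**2
        assert abs(circleish_fine.area - true) < abs(circleish_coarse.area - true)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ParameterError):
            buffer_region([box(0, 0, 1, 1)], 0.0)


class TestSharedBorderLength:
    def test_two_unit_squares(self):
        mosaic = [patch(0, 0, 1, 1, "cropland", "a"), patch(1, 0, 2, 1, "forest", "b")]
        assert shared_border_length(mosaic, box(0, 0, 2, 1)) == pytest.approx(1.0)

    def test_row_of_three(self):
        mosaic = [
            patch(0, 0, 1, 1, "cropland", "a"),
            patch(1, 0, 2, 1, "forest", "b"),
            patch(2, 0, 3, 1, "cropland", "c"),
        ]
        assert shared_border_length(mosaic, box(0, 0, 3, 1)) == pytest.approx(2.0)

    def test_single_patch_has_no_borders(self):
        assert shared_border_length([patch(0, 0, 1, 1, "forest", "a")]) == 0.0

    def test_same_class_edges_not_counted(self):
        mosaic = [patch(0, 0, 1, 1, "forest", "a"), patch(1, 0, 2, 1, "forest", "b")]
        assert shared_border_length(mosaic) == 0.0

    def test_window_clipping(self):
        mosaic = [patch(0, 0, 2, 2, "cropland", "a"), patch(2, 0, 4, 2, "forest", "b")]
        assert shared_border_length(mosaic, box(0, 0, 4, 1)) == pytest.approx(1.0)

    def test_scaling_doubles_length(self):
        mosaic = [patch(0, 0, 1, 1, "cropland", "a"), patch(1, 0, 2, 1, "forest", "b")]
        scaled = [
            LandCoverPatch(
                Polygon([(2 * x, 2 * y) for x, y in p.geometry.exterior.coords]),
                p.patch_class,
                p.patch_id,
            )
            for p in mosaic
        ]
        assert shared_border_length(scaled) == pytest.approx(
            2 * shared_border_length(mosaic)
        )

    def test_overlapping_mosaic_rejected(self):
        mosaic = [patch(0, 0, 2, 1, "cropland", "a"), patch(1, 0, 3, 1, "forest", "b")]
        with pytest.raises(InvalidMosaicError):
            shared_border_length(mosaic)


class TestMeanInteriorDistance:
    def test_single_centre_point(self):
        # 2x2 cropland ringed by forest; one grid point at the centre
        habitats = [
            patch(-10, -10, 0, 12, "forest", "w"),
            patch(2, -10, 12, 12, "forest", "e"),
            patch(0, 2, 2, 12, "forest", "n"),
            patch(0, -10, 2, 0, "forest", "s"),
        ]
        d = mean_interior_distance(box(0, 0, 2, 2), habitats, spacing=2.0)
        assert d == pytest.approx(1.0)

    def test_excluded_classes_force_farther_habitat(self):
        habitats = [
            patch(2, 0, 4, 2, "water", "w"),
            patch(-50, 0, -49, 2, "forest", "f"),  # nearest edge 50 m left of centre
        ]
        d = mean_interior_distance(box(0, 0, 2, 2), habitats,
                                   excluded_classes=("water", "built_up"), spacing=2.0)
        assert d == pytest.approx(50.0)  # centre point to forest edge

    def test_grid_equals_brute_force(self):
        target = box(0, 0, 100, 100)
        habitats = [
            patch(-10, -10, 0, 110, "forest", "w"),
            patch(100, -10, 110, 110, "forest", "e"),
            patch(0, 100, 100, 110, "forest", "n"),
            patch(0, -10, 100, 0, "forest", "s"),
        ]
        result = mean_interior_distance(target, habitats, spacing=10.0)
        pts = [(5 + 10 * i, 5 + 10 * j) for i in range(10) for j in range(10)]
        brute = np.mean(
            [min(x, y, 100 - x, 100 - y) for x, y in pts]
        )
        assert result == pytest.approx(brute, rel=1e-12)

    def test_spacing_halving_stays_within_5pct(self):
        target = box(0, 0, 100, 100)
        habitats = [
            patch(-10, -10, 0, 110, "forest", "w"),
            patch(100, -10, 110, 110, "forest", "e"),
        ]
        coarse = mean_interior_distance(target, habitats, spacing=10.0)
        fine = mean_interior_distance(target, habitats, spacing=5.0)
        assert abs(coarse - fine) / fine < 0.05

    def test_no_eligible_habitat_is_undefined(self):
        assert math.isnan(
            mean_interior_distance(box(0, 0, 2, 2), [patch(5, 0, 6, 1, "water", "w")],
                                   excluded_classes=("water",), spacing=1.0)
        )


class TestOverlayArea:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (box(0, 0, 2, 2), box(0, 0, 2, 2), 4.0),
            (box(0, 0, 1, 1), box(5, 5, 6, 6), 0.0),
            (box(0, 0, 1, 1), box(0.5, 0, 1, 1), 0.5),
        ],
    )
    def test_hand_overlays(self, a, b, expected):
        assert overlay_area(a, b) == pytest.approx(expected)

    def test_bounded_by_min_area(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = box(*np.sort(rng.uniform(0, 10, 2)), *np.sort(rng.uniform(0, 10, 2)))
            a = box(a.bounds[0], a.bounds[1], a.bounds[0] + 1 + a.bounds[2] % 3,
                    a.bounds[1] + 1 + a.bounds[3] % 3)
            b = translate(a, rng.uniform(-2, 2), rng.uniform(-2, 2))
            assert overlay_area(a, b) <= min(a.area, b.area) + 1e-9
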