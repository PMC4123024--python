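"""Geometry of buffer-variable extraction, checked against brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_road_scene
from _oracles import point_segment_distance_scalar

import multilur as ml
from multilur.buffers import (
    buffer_sum,
    nearest_road_intensity,
    point_segment_distance,
    raster_class_area_in_disc,
    ring_sum,
    segment_length_in_disc,
)
from multilur.errors import DataError
from multilur.types import LandUseRaster


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["segment_id", "x1", "y1", "x2", "y2",
                                       "intensity", "is_major"])


class TestSegmentLengthInDisc:
    def test_diameter_chord_is_2r(self):
        assert segment_length_in_disc(-10, 0, 10, 0, 0, 0, 5.0) == pytest.approx(10.0, abs=1e-12)

    def test_contained_segment_full_length(self):
        assert segment_length_in_disc(-3, 1, 4, 1, 0, 0, 50.0) == pytest.approx(7.0, abs=1e-12)

    def test_disjoint_segment_zero(self):
        assert segment_length_in_disc(100, 100, 200, 100, 0, 0, 5.0) == 0.0

    def test_zero_length_segment_is_point(self):
        assert segment_length_in_disc(1, 1, 1, 1, 0, 0, 10.0) == 0.0

    def test_oblique_partial_overlap_matches_monte_carlo(self):
        # fixed oblique segment partially crossing the disc boundary
        x1, y1, x2, y2, r = -40.0, -25.0, 60.0, 35.0, 30.0
        exact = segment_length_in_disc(x1, y1, x2, y2, 0.0, 0.0, r)
        rng = np.random.default_rng(7)
        t = rng.uniform(size=1_000_000)
        px, py = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
        inside = px * px + py * py <= r * r
        seg_len = np.hypot(x2 - x1, y2 - y1)
        frac = inside.mean()
        mc = frac * seg_len
        se = seg_len * np.sqrt(frac * (1 - frac) / len(t))
        assert abs(exact - mc) < 3 * se

    def test_tangent_line_contributes_zero(self):
        # line y = r touches the circle in one point: measure-zero overlap
        assert segment_length_in_disc(-10, 5, 10, 5, 0, 0, 5.0) == 0.0


class TestBufferSum:
    def test_empty_scene_zero(self):
        roads = seg_frame([])
        assert buffer_sum(roads, 0, 0, 100.0) == 0.0

    def test_contained_segment_traffic_load(self):
        roads = seg_frame([("R0", 0, 0, 100, 0, 5000.0, True)])
        assert buffer_sum(roads, 50, 0, 500.0, weight="intensity") == pytest.approx(5.0e5)
        assert buffer_sum(roads, 50, 0, 500.0, weight="unit") == pytest.approx(100.0)

    def test_major_only_filter(self):
        roads = seg_frame([("R0", 0, 0, 100, 0, 5000.0, False),
                           ("R1", 0, 10, 100, 10, 9000.0, True)])
        assert buffer_sum(roads, 50, 0, 500.0, major_only=True) == pytest.approx(100.0)

    def test_additivity_over_random_scene(self, rng):
        roads = random_road_scene(rng, n_segments=50)
        total = buffer_sum(roads, 0.0, 0.0, 800.0, weight="intensity")
        per_segment = sum(
            seg["intensity"] * segment_length_in_disc(
                seg["x1"], seg["y1"], seg["x2"], seg["y2"], 0.0, 0.0, 800.0)
            for _, seg in roads.iterrows()
        )
        assert total == pytest.approx(per_segment, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r=st.floats(50.0, 1500.0))
    def test_monotone_in_radius(self, seed, r):
        roads = random_road_scene(np.random.default_rng(seed), n_segments=20)
        assert buffer_sum(roads, 0, 0, r) <= buffer_sum(roads, 0, 0, r * 1.5) + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), dx=st.floats(-5e4, 5e4), dy=st.floats(-5e4, 5e4))
    def test_translation_invariance(self, seed, dx, dy):
        roads = random_road_scene(np.random.default_rng(seed), n_segments=15)
        moved = roads.copy()
        for c in ("x1", "x2"):
            moved[c] += dx
        for c in ("y1", "y2"):
            moved[c] += dy
        a = buffer_sum(roads, 10.0, -20.0, 700.0, weight="intensity")
        b = buffer_sum(moved, 10.0 + dx, -20.0 + dy, 700.0, weight="intensity")
        assert a == pytest.approx(b, rel=1e-9, abs=1e-6)

    def test_bounded_by_network_length(self, rng):
        roads = random_road_scene(rng, n_segments=30)
        network = np.hypot(roads.x2 - roads.x1, roads.y2 - roads.y1).sum()
        assert buffer_sum(roads, 0, 0, 1e6) <= network * (1 + 1e-12)


class TestRingSum:
    def test_all_roads_inside_inner_gives_zero(self):
        roads = seg_frame([("R0", -10, 0, 10, 0, 100.0, False)])
        assert ring_sum(roads, 0, 0, 50.0, 1000.0) == 0.0

    def test_invalid_radii_rejected(self):
        roads = seg_frame([("R0", -10, 0, 10, 0, 100.0, False)])
        with pytest.raises(ValueError):
            ring_sum(roads, 0, 0, 1000.0, 50.0)

    def test_ring_plus_inner_equals_outer(self, rng):
        for _ in range(20):
            roads = random_road_scene(rng, n_segments=25)
            inner, outer = 50.0, 1000.0
            lhs = (ring_sum(roads, 0, 0, inner, outer, weight="intensity")
                   + buffer_sum(roads, 0, 0, inner, weight="intensity"))
            rhs = buffer_sum(roads, 0, 0, outer, weight="intensity")
            assert abs(lhs - rhs) <= 1e-9 * max(1.0, abs(rhs))


class TestNearestRoadIntensity:
    def test_single_segment(self):
        roads = seg_frame([("R0", 0, 10, 100, 10, 4321.0, False)])
        assert nearest_road_intensity(roads, 50, 0) == 4321.0

    def test_tie_broken_by_smallest_segment_id(self):
        roads = seg_frame([("R2", 0, 10, 100, 10, 111.0, False),
                           ("R1", 0, -10, 100, -10, 222.0, False)])
        assert nearest_road_intensity(roads, 50, 0) == 222.0

    def test_empty_scene_is_error(self):
        with pytest.raises(DataError):
            nearest_road_intensity(seg_frame([]), 0, 0)

    def test_matches_exhaustive_scan(self, rng):
        roads = random_road_scene(rng, n_segments=100)
        for _ in range(20):
            px, py = rng.uniform(-2000, 2000, size=2)
            dists = [point_segment_distance_scalar(px, py, s.x1, s.y1, s.x2, s.y2)
                     for s in roads.itertuples()]
            expected = roads["intensity"].iloc[int(np.argmin(dists))]
            assert nearest_road_intensity(roads, px, py) == expected


class TestPointSegmentDistance:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100),
           st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100))
    def test_matches_scalar_reference(self, px, py, x1, y1, x2, y2):
        got = point_segment_distance(px, py, x1, y1, x2, y2)
        want = point_segment_distance_scalar(px, py, x1, y1, x2, y2)
        assert got == pytest.approx(want, abs=1e-9)


class TestRasterArea:
    def _uniform(self, n=200, cs=10.0):
        return LandUseRaster(x0=-n * cs / 2, y0=-n * cs / 2, cell_size=cs,
                             grid=np.full((n, n), 2))

    def test_uniform_raster_approximates_disc_area(self):
        r = 300.0
        raster = self._uniform()
        got = raster_class_area_in_disc(raster, 0, 0, r, {2})
        ring = np.pi * ((r + raster.cell_size * np.sqrt(2)) ** 2
                        - (r - raster.cell_size * np.sqrt(2)) ** 2)
        assert abs(got - np.pi * r * r) < ring

    def test_empty_class_set_zero(self):
        assert raster_class_area_in_disc(self._uniform(), 0, 0, 100, set()) == 0.0

    def test_outside_extent_zero(self):
        assert raster_class_area_in_disc(self._uniform(), 1e6, 1e6, 100, {2}) == 0.0

    def test_matches_per_cell_brute_force(self, rng):
        n, cs = 40, 25.0
        grid = rng.integers(0, 3, size=(n, n))
        raster = LandUseRaster(x0=0.0, y0=0.0, cell_size=cs, grid=grid)
        cx, cy, r = 480.0, 530.0, 310.0
        count = 0
        for row in range(n):
            for col in range(n):
                x = 0.0 + (col + 0.5) * cs
                y = 0.0 + (n - 1 - row + 0.5) * cs
                if (x - cx) ** 2 + (y - cy) ** 2 <= r * r and grid[row, col] in (1, 2):
                    count += 1
        got = raster_class_area_in_disc(raster, cx, cy, r, {1, 2})
        assert got == count * cs * cs

    def test_monotone_in_radius(self, rng):
        raster = LandUseRaster(x0=0, y0=0, cell_size=50.0,
                               grid=rng.integers(0, 3, size=(60, 60)))
        radii = [100.0, 300.0, 700.0, 1400.0]
        vals = [raster_class_area_in_disc(raster, 1500, 1500, r, {2}) for r in radii]
        assert vals == sorted(vals)
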