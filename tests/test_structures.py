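"""Contour/mask conversion, post-processing, distance fields and margin expansion."""

import numpy as np
import pytest

from doseval.grid import ContourSlice, ContourStack, Grid3D, MarginSpec, StructureMask
from doseval.structures import (
    contours_to_mask,
    expand_margin,
    mask_to_contours,
    remove_3d_outliers,
    signed_distance,
    smooth_contours,
)

from conftest import make_grid, make_mask, random_blob


def square_stack(side_mm=10.0, z=0.0, name="sq"):
    poly = np.array([[0, 0], [0, side_mm], [side_mm, side_mm], [side_mm, 0]], float)
    return ContourStack(name, [ContourSlice(z, [poly])])


class TestContoursToMask:
    def test_unit_square_rasterizes_to_exact_area(self):
        # centers 0.5 .. 9.5 all strictly inside the 10 mm square
        grid = Grid3D((1, 12, 12), (1.0, 1.0, 1.0), (0.0, 0.5, 0.5))
        mask = contours_to_mask(square_stack(), grid)
        assert mask.voxel_count == 100
        assert mask.volume_mm3 == pytest.approx(100.0)

    def test_empty_stack_gives_empty_mask(self):
        grid = make_grid()
        mask = contours_to_mask(ContourStack("none", []), grid)
        assert mask.is_empty

    def test_z_outside_grid_reports_slice(self):
        grid = make_grid((2, 12, 12))
        with pytest.raises(ValueError, match="z = 50"):
            contours_to_mask(square_stack(z=50.0), grid)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="N>=3"):
            ContourSlice(0.0, [np.array([[0.0, 0.0], [1.0, 1.0]])])

    def test_even_odd_rule_leaves_hole(self):
        grid = Grid3D((1, 22, 22), (1, 1, 1), (0, 0.5, 0.5))
        outer = np.array([[1, 1], [1, 19], [19, 19], [19, 1]], float)
        inner = np.array([[6, 6], [6, 14], [14, 14], [14, 6]], float)
        mask = contours_to_mask(ContourStack("ann", [ContourSlice(0.0, [outer, inner])]), grid)
        assert mask.voxel_count == 18 * 18 - 8 * 8
        assert not mask.voxels[0, 10, 10]


class TestMaskToContours:
    def test_single_voxel_gives_diamond(self):
        # marching squares at level 0.5 crosses the four edge midpoints
        grid = make_grid((1, 5, 5))
        mask = make_mask(grid, [(0, 2, 2)])
        stack = mask_to_contours(mask)
        assert len(stack.slices) == 1
        (poly,) = stack.slices[0].polygons
        closed = np.vstack([poly, poly[:1]])
        perim = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        assert perim == pytest.approx(2 * np.sqrt(2.0), abs=1e-9)
        assert poly.mean(axis=0) == pytest.approx([2.0, 2.0], abs=1e-9)

    def test_two_slice_cylinder_one_polygon_per_slice(self):
        grid = make_grid((4, 16, 16))
        v = np.zeros(grid.shape, bool)
        yy, xx = np.mgrid[:16, :16]
        disc = (yy - 8) ** 2 + (xx - 8) ** 2 <= 25
        v[1] = v[2] = disc
        stack = mask_to_contours(StructureMask("cyl", grid, v))
        assert len(stack.slices) == 2
        assert all(len(s.polygons) == 1 for s in stack.slices)

    def test_annulus_yields_outer_ccw_and_inner_cw(self):
        grid = make_grid((1, 24, 24))
        yy, xx = np.mgrid[:24, :24]
        r = np.hypot(yy - 12, xx - 12)
        v = ((r < 9) & (r > 4))[None]
        stack = mask_to_contours(StructureMask("ann", grid, v))
        polys = stack.slices[0].polygons
        assert len(polys) == 2

        def signed_area(p):
            y, x = p[:, 0], p[:, 1]
            return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

        areas = sorted(signed_area(p) for p in polys)
        assert areas[0] < 0 < areas[1]  # one hole (cw), one outer (ccw)
        assert abs(areas[1]) > abs(areas[0])

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_contours(make_mask(make_grid(), []))

    def test_round_trip_solid_block_is_exact(self):
        grid = make_grid((5, 8, 8))
        v = np.zeros(grid.shape, bool)
        v[1:4, 2:7, 2:7] = True
        mask = StructureMask("b", grid, v)
        rt = contours_to_mask(mask_to_contours(mask), grid)
        assert np.array_equal(rt.voxels, v)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_round_trip_random_blobs(self, seed):
        grid = Grid3D((10, 24, 24), (2.0, 1.5, 1.5), (-4.0, 0.0, 0.0))
        blob = random_blob(grid, np.random.default_rng(seed))
        rt = contours_to_mask(mask_to_contours(blob), grid)
        assert np.array_equal(rt.voxels, blob.voxels)


class TestOutlierRemoval:
    def test_keeps_largest_component(self):
        grid = make_grid((6, 10, 10))
        v = np.zeros(grid.shape, bool)
        v[1:4, 1:6, 1:6] = True  # 75 voxels
        v[5, 8, 8] = v[5, 8, 9] = True  # 2-voxel blob
        out = remove_3d_outliers(StructureMask("m", grid, v))
        assert out.voxel_count == 75
        assert not out.voxels[5, 8, 8]

    def test_single_component_unchanged(self):
        grid = make_grid()
        m = make_mask(grid, [(1, 1, 1), (1, 1, 2), (2, 2, 2)])  # 26-connected
        out = remove_3d_outliers(m)
        assert np.array_equal(out.voxels, m.voxels)

    def test_tie_breaks_to_smallest_lexicographic_index(self):
        grid = make_grid()
        m = make_mask(grid, [(0, 0, 5), (5, 5, 0)])  # two equal single-voxel components
        out = remove_3d_outliers(m)
        assert out.voxels[0, 0, 5] and not out.voxels[5, 5, 0]

    def test_empty_passes_through(self):
        out = remove_3d_outliers(make_mask(make_grid(), []))
        assert out.is_empty

    @pytest.mark.parametrize("seed", [0, 7])
    def test_idempotent(self, seed):
        grid = make_grid((8, 16, 16))
        rng = np.random.default_rng(seed)
        v = rng.random(grid.shape) > 0.7
        once = remove_3d_outliers(StructureMask("m", grid, v))
        twice = remove_3d_outliers(once)
        assert np.array_equal(once.voxels, twice.voxels)
        assert once.voxel_count <= int(v.sum())


class TestSmoothContours:
    def test_window_one_is_identity(self):
        stack = square_stack()
        out = smooth_contours(stack, window=1)
        assert np.allclose(out.slices[0].polygons[0], stack.slices[0].polygons[0])

    def test_square_perimeter_strictly_decreases(self):
        # dense square so the moving average pulls corners inward
        t = np.linspace(0, 40, 80, endpoint=False)
        side = 10.0
        pts = []
        for u in t:
            k, f = int(u // side), (u % side)
            pts.append([[f, 0], [side, f], [side - f, side], [0, side - f]][k])
        poly = np.array(pts, float)[:, ::-1]
        stack = ContourStack("sq", [ContourSlice(0.0, [poly])])

        def perim(p):
            closed = np.vstack([p, p[:1]])
            return np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))

        out = smooth_contours(stack, window=3)
        assert len(out.slices[0].polygons[0]) == len(poly)
        assert perim(out.slices[0].polygons[0]) < perim(poly)

    def test_circle_centroid_preserved(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        poly = np.column_stack([5 + 3 * np.sin(t), 5 + 3 * np.cos(t)])
        out = smooth_contours(ContourStack("c", [ContourSlice(0.0, [poly])]), window=5)
        assert np.allclose(out.slices[0].polygons[0].mean(axis=0), [5.0, 5.0], atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_contours(square_stack(), window=4)


class TestExpandMargin:
    def test_single_voxel_isotropic_one_mm(self):
        grid = make_grid((5, 5, 5))
        ptv = expand_margin(make_mask(grid, [(2, 2, 2)], "CTV"), MarginSpec.isotropic(1.0))
        assert ptv.voxel_count == 7  # center + six face neighbours

    def test_zero_margins_identity(self):
        grid = make_grid((5, 5, 5))
        ctv = make_mask(grid, [(2, 2, 2), (2, 2, 3)], "CTV")
        ptv = expand_margin(ctv, MarginSpec.isotropic(0.0))
        assert np.array_equal(ptv.voxels, ctv.voxels)

    def test_zero_posterior_margin_drops_posterior_neighbour(self):
        grid = make_grid((5, 5, 5))
        ptv = expand_margin(
            make_mask(grid, [(2, 2, 2)], "CTV"),
            MarginSpec(anterior=1, posterior=0, left=1, right=1, superior=1, inferior=1),
        )
        assert ptv.voxel_count == 6
        assert not ptv.voxels[2, 3, 2]  # +y (posterior) neighbour absent
        assert ptv.voxels[2, 1, 2]  # -y (anterior) neighbour present

    def test_empty_ctv_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            expand_margin(make_mask(make_grid(), []), MarginSpec.isotropic(1))

    def test_monotone_in_margins_and_superset(self):
        grid = Grid3D((12, 20, 20), (2.0, 1.5, 1.5))
        blob = random_blob(grid, np.random.default_rng(5))
        prev = blob.voxels
        for m in (0.0, 2.0, 4.0, 6.0):
            ptv = expand_margin(blob, MarginSpec.isotropic(m))
            assert np.all(ptv.voxels | ~prev)  # superset of the previous level
            assert np.all(ptv.voxels | ~blob.voxels)  # always contains the CTV
            prev = ptv.voxels


class TestSignedDistance:
    def test_face_adjacent_inside_voxel_value(self):
        grid = make_grid((5, 5, 5))
        v = np.zeros(grid.shape, bool)
        v[1:4, 1:4, 1:4] = True
        sd = signed_distance(StructureMask("m", grid, v))
        assert -1.5 <= sd[2, 2, 1] <= -0.5  # inside, face-adjacent to boundary
        assert sd[2, 2, 0] == pytest.approx(1.0)  # first outside voxel

    def test_threshold_zero_reproduces_mask(self, rng):
        grid = Grid3D((10, 16, 16), (2.0, 1.0, 1.0))
        blob = random_blob(grid, np.random.default_rng(11))
        sd = signed_distance(blob)
        assert np.array_equal(sd < 0, blob.voxels)

    @pytest.mark.parametrize("margin", [1.0, 2.5])
    def test_threshold_at_m_equals_isotropic_expansion(self, margin):
        grid = Grid3D((10, 16, 16), (2.0, 1.0, 1.0))
        blob = random_blob(grid, np.random.default_rng(13))
        sd = signed_distance(blob)
        ptv = expand_margin(blob, MarginSpec.isotropic(margin))
        assert np.array_equal(sd <= margin, ptv.voxels)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            signed_distance(make_mask(make_grid(), []))


class TestGridValidation:
    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            Grid3D((2, 2, 2), (1.0, 0.0, 1.0))

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            MarginSpec(anterior=-1)

    def test_compatibility_tolerance(self):
        a = Grid3D((2, 2, 2), (1, 1, 1), (0, 0, 0))
        b = Grid3D((2, 2, 2), (1, 1, 1), (0, 0, 1e-7))
        c = Grid3D((2, 2, 2), (1, 1, 1), (0, 0, 0.5))
        assert a.compatible_with(b)
        assert not a.compatible_with(c)
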