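"""Rasterization, bone thresholding, flattening and their oracles."""

import numpy as np
import pytest

from rtname import voxelize
from rtname.datatypes import BoundingBox, BinaryVolume, Contour, StructureRecord

from _oracles import point_in_polygon, rasterize_bruteforce, random_simple_polygon
from conftest import make_series


def _record(contours):
    return StructureRecord(given_name="x", contours=contours)


class TestBoundingBox:
    def test_spans_voxel_outer_corners(self):
        series = make_series(nx=96, ny=96, nz=48, spacing=(1, 1, 2), origin=(0, 0, 0))
        box = voxelize.compute_bounding_box(series)
        assert np.allclose(box.min_corner, [-0.5, -0.5, -1.0])
        assert np.allclose(box.max_corner, [95.5, 95.5, 95.0])

    def test_single_slice_is_degenerate(self):
        series = make_series(nz=1)
        with pytest.raises(ValueError, match="degenerate extent"):
            voxelize.compute_bounding_box(series)

    def test_matches_corner_enumeration_oracle(self, rng):
        for _ in range(10):
            origin = rng.uniform(-50, 50, 3)
            spacing = rng.uniform(0.5, 4.0, 3)
            dims = rng.integers(2, 12, 3)
            series = make_series(nx=dims[0], ny=dims[1], nz=dims[2],
                                 spacing=spacing, origin=origin)
            box = voxelize.compute_bounding_box(series)
            # enumerate all 8 corners of every voxel
            corners = []
            for i in range(dims[0]):
                for j in range(dims[1]):
                    for k in range(dims[2]):
                        c = origin + np.array([i, j, k]) * spacing
                        for s in np.ndindex(2, 2, 2):
                            corners.append(c + (np.array(s) - 0.5) * spacing)
            corners = np.array(corners)
            assert np.allclose(box.min_corner, corners.min(axis=0))
            assert np.allclose(box.max_corner, corners.max(axis=0))


class TestRasterize:
    BOX = BoundingBox(np.zeros(3), np.array([4.0, 4.0, 4.0]))

    def test_square_with_four_interior_centers(self):
        # centers of the 4x4 grid sit at 0.5..3.5; this square contains
        # exactly the four centers at 1.5 and 2.5 (verified by the oracle)
        square = np.array([[1.1, 1.1], [2.9, 1.1], [2.9, 2.9], [1.1, 2.9]])
        rec = _record([Contour(slice_z=0.5, points=square)])
        vol = voxelize.rasterize_structure(rec, self.BOX, (4, 4, 4))
        oracle = rasterize_bruteforce(square, 0.5, self.BOX.min_corner, self.BOX.max_corner, (4, 4, 4))
        assert oracle.sum() == 4
        assert np.array_equal(vol.bits, oracle)

    def test_empty_contours_all_zero(self):
        vol = voxelize.rasterize_structure(_record([]), self.BOX, (4, 4, 4))
        assert vol.bits.sum() == 0

    def test_default_grid_flattens_to_442368(self):
        vol = voxelize.rasterize_structure(_record([]), self.BOX)
        assert voxelize.flatten(vol).shape == (442368,)

    def test_degenerate_contour_skipped_with_warning(self):
        rec = _record([Contour(slice_z=0.5, points=np.array([[0, 0], [1, 1]]))])
        with pytest.warns(UserWarning, match="fewer than 3"):
            vol = voxelize.rasterize_structure(rec, self.BOX, (4, 4, 4))
        assert vol.bits.sum() == 0

    def test_contour_outside_box_clipped(self):
        square = np.array([[1, 1], [3, 1], [3, 3], [1, 3]], dtype=float)
        rec = _record([Contour(slice_z=99.0, points=square)])
        vol = voxelize.rasterize_structure(rec, self.BOX, (4, 4, 4))
        assert vol.bits.sum() == 0

    def test_matches_bruteforce_oracle_on_random_polygons(self, rng):
        box = BoundingBox(np.array([-6.0, -6.0, 0.0]), np.array([6.0, 6.0, 4.0]))
        grid = (12, 12, 4)
        for _ in range(100):
            poly = random_simple_polygon(rng, n_vertices=int(rng.integers(3, 12)))
            z = rng.uniform(0, 4)
            rec = _record([Contour(slice_z=z, points=poly)])
            vol = voxelize.rasterize_structure(rec, box, grid)
            oracle = rasterize_bruteforce(poly, z, box.min_corner, box.max_corner, grid)
            assert np.array_equal(vol.bits, oracle)

    def test_scaling_a_convex_contour_is_monotone(self, rng):
        box = BoundingBox(np.array([-10.0, -10.0, 0.0]), np.array([10.0, 10.0, 2.0]))
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        prev = -1
        for scale in (1.0, 1.5, 2.2, 3.0, 4.5):
            pts = np.column_stack([scale * np.cos(theta), scale * np.sin(theta)])
            vol = voxelize.rasterize_structure(_record([Contour(1.0, pts)]), box, (20, 20, 2))
            count = int(vol.bits.sum())
            assert count >= prev
            prev = count

    def test_translation_by_exact_pitch_shifts_pattern(self):
        box = BoundingBox(np.zeros(3), np.array([16.0, 16.0, 2.0]))
        grid = (16, 16, 2)  # pitch 1 mm
        poly = np.array([[3.2, 3.2], [6.8, 3.4], [5.5, 7.1]])
        v0 = voxelize.rasterize_structure(_record([Contour(0.5, poly)]), box, grid)
        v1 = voxelize.rasterize_structure(_record([Contour(0.5, poly + [2.0, 3.0])]), box, grid)
        assert np.array_equal(np.roll(np.roll(v0.bits, 2, axis=0), 3, axis=1), v1.bits)


class TestBone:
    @pytest.mark.parametrize("hu,expected", [(1299, 0), (1300, 0), (1301, 1)])
    def test_threshold_is_exclusive(self, hu, expected):
        voxels = np.full((6, 8, 8), hu, dtype=np.int16)
        series = make_series(voxels=voxels)
        box = voxelize.compute_bounding_box(series)
        vol = voxelize.extract_bony_anatomy(series, box, (8, 8, 6))
        assert vol.bits.min() == vol.bits.max() == expected

    def test_air_phantom_all_zero(self):
        series = make_series(voxels=np.full((6, 8, 8), -1000, dtype=np.int16))
        box = voxelize.compute_bounding_box(series)
        assert voxelize.extract_bony_anatomy(series, box, (4, 4, 3)).bits.sum() == 0

    def test_matches_nearest_neighbour_oracle(self, rng):
        voxels = rng.integers(-1000, 2000, size=(6, 10, 9)).astype(np.int16)
        series = make_series(nx=9, ny=10, nz=6, spacing=(1.5, 2.0, 2.5), voxels=voxels)
        box = voxelize.compute_bounding_box(series)
        grid = (5, 7, 4)
        vol = voxelize.extract_bony_anatomy(series, box, grid, threshold_hu=700)
        cell = box.size / np.array(grid)
        for i in range(grid[0]):
            for j in range(grid[1]):
                for k in range(grid[2]):
                    c = box.min_corner + (np.array([i, j, k]) + 0.5) * cell
                    idx = np.rint((c - series.origin) / series.spacing).astype(int)
                    idx = np.clip(idx, 0, np.array([8, 9, 5]))
                    hu = voxels[idx[2], idx[1], idx[0]]
                    assert vol.bits[i, j, k] == (1 if hu > 700 else 0)


class TestFlatten:
    def test_roundtrip_identity(self, rng):
        box = BoundingBox(np.zeros(3), np.array([5.0, 4.0, 3.0]))
        bits = rng.integers(0, 2, size=(5, 4, 3)).astype(np.uint8)
        vol = BinaryVolume(bits, box)
        flat = voxelize.flatten(vol)
        back = voxelize.unflatten(flat, (5, 4, 3), box)
        assert np.array_equal(back.bits, bits)

    def test_order_is_slab_major(self):
        bits = np.zeros((3, 2, 2), dtype=np.uint8)
        bits[1, 0, 0] = 1  # i=1, j=0, k=0 -> flat index k*(ny*nx) + j*nx + i = 1
        vol = BinaryVolume(bits, BoundingBox(np.zeros(3), np.array([3.0, 2.0, 2.0])))
        assert voxelize.flatten(vol)[1] == 1

    def test_zero_volume_flattens_to_zero_vector(self):
        vol = BinaryVolume(np.zeros((2, 2, 2), np.uint8),
                           BoundingBox(np.zeros(3), np.ones(3) * 2))
        assert not voxelize.flatten(vol).any()


class TestConcat:
    def test_lengths_and_halves(self, rng):
        a = rng.integers(0, 2, 10)
        b = rng.integers(0, 2, 10)
        c = voxelize.concat_structure_and_bone(a, b)
        assert len(c) == 20
        assert np.array_equal(c[:10], a) and np.array_equal(c[10:], b)

    def test_default_lengths_concatenate_to_884736(self):
        c = voxelize.concat_structure_and_bone(np.zeros(442368, np.uint8),
                                               np.zeros(442368, np.uint8))
        assert len(c) == 884736

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voxelize.concat_structure_and_bone(np.zeros(4), np.zeros(5))
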