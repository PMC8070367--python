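"""Geometric featurization: contours and bony anatomy to binary occupancy grids.

Every structure is rendered onto a fixed grid (default 96 x 96 x 48) that
spans the planning image's bounding box, then flattened to a {0,1} feature
vector (default length 442,368). Bony anatomy is obtained by thresholding
the CT at 1300 HU and resampling onto the same grid, adding skeletal
context to the structure's location.

Conventions (fixed so that serialized SVD models stay valid):

* A grid cell is set iff its *centre* lies inside or on the boundary of a
  filled contour polygon; boundary centres count as inside.
* A contour at height z belongs to the grid slab whose z-interval contains
  z; multiple polygons landing in one slab are OR-combined.
* Contours (or parts of contours) outside the image box are clipped
  silently — real plans contain couch and marker structures beyond the
  field of view.
* Flattening is slab-major: flat index = (k * ny + j) * nx + i, with k
  (z) slowest and i (x) fastest.
* The HU threshold is exclusive: exactly 1300 HU maps to 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely

from .datatypes import BinaryVolume, BoundingBox, ImageSeries, StructureRecord, DEFAULT_GRID_SHAPE

__all__ = [
    "compute_bounding_box",
    "rasterize_structure",
    "extract_bony_anatomy",
    "flatten",
    "unflatten",
    "concat_structure_and_bone",
    "DEFAULT_HU_THRESHOLD",
]

DEFAULT_HU_THRESHOLD = 1300.0


def compute_bounding_box(series: ImageSeries) -> BoundingBox:
    """Outer-corner bounding box of the planning image.

    Spans from the first voxel centre minus half a voxel pitch to the last
    voxel centre plus half a pitch, so the box covers whole voxels.
    """
    nx, ny, nz = series.shape_xyz
    if nz < 2:
        raise ValueError("degenerate extent: series needs >= 2 slices")
    dims = np.array([nx, ny, nz], dtype=float)
    lo = series.origin - series.spacing / 2.0
    hi = series.origin + (dims - 1) * series.spacing + series.spacing / 2.0
    return BoundingBox(lo, hi)


def _cell_size(box: BoundingBox, grid_shape) -> np.ndarray:
    return box.size / np.asarray(grid_shape, dtype=float)


def _axis_centers(box: BoundingBox, grid_shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cell = _cell_size(box, grid_shape)
    return tuple(
        box.min_corner[a] + (np.arange(grid_shape[a]) + 0.5) * cell[a] for a in range(3)
    )


def rasterize_structure(
    record: StructureRecord,
    box: BoundingBox,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
) -> BinaryVolume:
    """Fill a structure's closed contour polygons into an occupancy grid.

    A cell (i, j, k) is 1 iff its centre lies inside (or on the boundary
    of) some polygon assigned to slab k. An empty contour list yields an
    all-zero volume; degenerate contours (< 3 points) are skipped with a
    warning.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if min(grid_shape) < 1:
        raise ValueError("grid_shape components must be >= 1")
    bits = np.zeros(grid_shape, dtype=np.uint8)
    cell = _cell_size(box, grid_shape)
    xs, ys, _ = _axis_centers(box, grid_shape)

    for contour in record.contours:
        pts = contour.points
        if len(pts) < 3:
            warnings.warn("skipping contour with fewer than 3 points", stacklevel=2)
            continue
        k = int(np.floor((contour.slice_z - box.min_corner[2]) / cell[2]))
        if k < 0 or k >= grid_shape[2]:
            continue  # clipped: outside the planning-image box in z
        poly = shapely.Polygon(pts)
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        if poly.is_empty:
            continue
        minx, miny, maxx, maxy = poly.bounds
        i0, i1 = np.searchsorted(xs, [minx, maxx]) + [0, 1]
        j0, j1 = np.searchsorted(ys, [miny, maxy]) + [0, 1]
        i0, i1 = max(i0 - 1, 0), min(i1, grid_shape[0])
        j0, j1 = max(j0 - 1, 0), min(j1, grid_shape[1])
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        bits[i0:i1, j0:j1, k] |= inside.astype(np.uint8)
    return BinaryVolume(bits, box)


def extract_bony_anatomy(
    series: ImageSeries,
    box: BoundingBox,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    threshold_hu: float = DEFAULT_HU_THRESHOLD,
) -> BinaryVolume:
    """Threshold the CT at ``threshold_hu`` (strict >) and resample the mask
    onto the target grid by nearest-neighbour sampling at cell centres."""
    if not np.isfinite(threshold_hu):
        raise ValueError("threshold_hu must be finite")
    grid_shape = tuple(int(g) for g in grid_shape)
    xs, ys, zs = _axis_centers(box, grid_shape)
    nx, ny, nz = series.shape_xyz
    ix = np.clip(np.rint((xs - series.origin[0]) / series.spacing[0]).astype(int), 0, nx - 1)
    iy = np.clip(np.rint((ys - series.origin[1]) / series.spacing[1]).astype(int), 0, ny - 1)
    iz = np.clip(np.rint((zs - series.origin[2]) / series.spacing[2]).astype(int), 0, nz - 1)
    # voxels are stored [k, j, i]; build the sampled volume indexed [i, j, k]
    sampled = series.voxels[np.ix_(iz, iy, ix)].transpose(2, 1, 0)
    bits = (sampled > threshold_hu).astype(np.uint8)
    return BinaryVolume(bits, box)


def flatten(volume: BinaryVolume) -> np.ndarray:
    """Flatten an occupancy grid to a 1D {0,1} vector, slab-major (k slowest,
    then j, then i). For the default grid the length is 442,368."""
    return np.ascontiguousarray(volume.bits.transpose(2, 1, 0)).ravel()


def unflatten(values: np.ndarray, grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
              box: BoundingBox | None = None) -> BinaryVolume:
    """Inverse of :func:`flatten`."""
    values = np.asarray(values)
    nx, ny, nz = grid_shape
    if values.size != nx * ny * nz:
        raise ValueError("length does not match grid shape")
    bits = values.reshape(nz, ny, nx).transpose(2, 1, 0)
    if box is None:
        box = BoundingBox(np.zeros(3), np.asarray(grid_shape, dtype=float))
    return BinaryVolume(bits, box)


def concat_structure_and_bone(structure_vec: np.ndarray, bone_vec: np.ndarray) -> np.ndarray:
    """Concatenate the structure occupancy vector with the bony-anatomy
    vector (structure first); both halves must have equal length."""
    structure_vec = np.asarray(structure_vec)
    bone_vec = np.asarray(bone_vec)
    if structure_vec.shape != bone_vec.shape or structure_vec.ndim != 1:
        raise ValueError("structure and bone vectors must be 1D of equal length")
    return np.concatenate([structure_vec, bone_vec])
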