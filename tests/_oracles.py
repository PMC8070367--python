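"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (shapely, randomized SVD, the
vectorised metric tally) used by the package.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon(px: float, py: float, polygon: np.ndarray) -> bool:
    """Scalar crossing-number membership test; points on an edge count as
    inside. ``polygon`` is (n, 2), implicitly closed."""
    n = len(polygon)
    inside = False
    for a in range(n):
        x1, y1 = polygon[a]
        x2, y2 = polygon[(a + 1) % n]
        # on-segment check
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def rasterize_bruteforce(polygon: np.ndarray, slice_z: float, box_min, box_max,
                         grid_shape) -> np.ndarray:
    """Loop over every grid-cell centre and test membership per point."""
    box_min = np.asarray(box_min, dtype=float)
    box_max = np.asarray(box_max, dtype=float)
    gs = np.asarray(grid_shape)
    cell = (box_max - box_min) / gs
    bits = np.zeros(tuple(gs), dtype=np.uint8)
    k = int(np.floor((slice_z - box_min[2]) / cell[2]))
    if not (0 <= k < gs[2]):
        return bits
    for i in range(gs[0]):
        for j in range(gs[1]):
            cx = box_min[0] + (i + 0.5) * cell[0]
            cy = box_min[1] + (j + 0.5) * cell[1]
            if point_in_polygon(cx, cy, polygon):
                bits[i, j, k] = 1
    return bits


def metrics_tally(counts: np.ndarray):
    """Per-class TP/FP/FN tally with explicit python loops, returning
    (macro_precision, macro_recall, macro_f1, accuracy) over the union of
    labels present in truth or prediction."""
    n = counts.shape[0]
    present = [c for c in range(n) if counts[c, :].sum() + counts[:, c].sum() > 0]
    precs, recs, f1s = [], [], []
    for c in present:
        tp = counts[c, c]
        fp = sum(counts[r, c] for r in range(n)) - tp
        fn = sum(counts[c, r] for r in range(n)) - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(f)
    acc = sum(counts[c, c] for c in range(n)) / counts.sum()
    return (float(np.mean(precs)), float(np.mean(recs)), float(np.mean(f1s)), float(acc))


def random_simple_polygon(rng: np.random.Generator, n_vertices: int = 8,
                          center=(0.0, 0.0), r_min: float = 1.0, r_max: float = 5.0) -> np.ndarray:
    """Star-shaped (hence simple) polygon: sorted angles, random radii."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(r_min, r_max, size=n_vertices)
    return np.column_stack([center[0] + radii * np.cos(angles),
                            center[1] + radii * np.sin(angles)])
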