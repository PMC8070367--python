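"""Truncated SVD of the (sparse, binary) geometric feature matrix.

The occupancy vectors are not mean-centred before decomposition: centering
would densify the matrix and the leading singular directions of the raw
{0,1} matrix are exactly what the downstream classifiers consume.

Solver choice: for small problems (n * d <= 4e6 entries) the
decomposition is computed exactly with dense LAPACK and truncated; for
the full-size feature matrices a seeded randomized range-finder is used
for speed. A
fixed sign convention (the largest-magnitude entry of every component is
made positive, ties resolved to the first index) makes serialized models
reproducible across solvers and runs.

The model is always fit on training rows only; held-out rows are projected
with the frozen components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

__all__ = ["SvdModel", "fit_truncated_svd", "transform", "truncate",
           "save_svd_model", "load_svd_model"]

_DENSE_ENTRY_LIMIT = 4_000_000


@dataclass
class SvdModel:
    """Top-k right singular subspace of the training matrix."""

    components: np.ndarray        # (k, d), rows orthonormal
    singular_values: np.ndarray   # (k,), descending
    k: int
    d: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        self.singular_values = np.asarray(self.singular_values, dtype=np.float64)
        if self.components.shape != (self.k, self.d):
            raise ValueError("components shape must be (k, d)")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be sorted descending")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(len(components)), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_truncated_svd(matrix, k: int, seed: int = 0) -> SvdModel:
    """Fit the top-k right singular subspace of ``matrix`` (n x d, dense or
    sparse). ``k`` must satisfy 1 <= k <= min(n, d)."""
    n, d = matrix.shape
    if not (1 <= k <= min(n, d)):
        raise ValueError(f"k={k} out of range for a {n}x{d} matrix")
    if n * d <= _DENSE_ENTRY_LIMIT:
        dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=np.float64)
        _, s, vt = np.linalg.svd(dense, full_matrices=False)
        s, vt = s[:k], vt[:k]
    else:
        _, s, vt = randomized_svd(matrix, n_components=k, n_iter=7, random_state=seed)
    return SvdModel(components=_fix_signs(vt), singular_values=s, k=k, d=d, seed=seed)


def transform(model: SvdModel, vec: np.ndarray):
    """Project a feature vector (length d) — or an (n, d) matrix of rows —
    onto the model's components."""
    if sp.issparse(vec):
        if vec.shape[1] != model.d:
            raise ValueError(f"expected {model.d} columns, got {vec.shape[1]}")
        return np.asarray(vec @ model.components.T)
    vec = np.asarray(vec, dtype=np.float64)
    if vec.shape[-1] != model.d:
        raise ValueError(f"expected length {model.d}, got {vec.shape[-1]}")
    return vec @ model.components.T


def truncate(model: SvdModel, k: int) -> SvdModel:
    """Keep only the leading ``k`` components of a fitted model."""
    if not (1 <= k <= model.k):
        raise ValueError(f"k={k} out of range for a rank-{model.k} model")
    return SvdModel(components=model.components[:k].copy(),
                    singular_values=model.singular_values[:k].copy(),
                    k=k, d=model.d, seed=model.seed)


def save_svd_model(model: SvdModel, path: str | Path) -> None:
    header = json.dumps({"format_version": 1, "k": model.k, "d": model.d,
                         "seed": model.seed, "sign_convention": "max-abs-positive"})
    np.savez_compressed(str(path), header=np.frombuffer(header.encode(), dtype=np.uint8),
                        components=model.components, singular_values=model.singular_values)


def load_svd_model(path: str | Path) -> SvdModel:
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        return SvdModel(components=z["components"], singular_values=z["singular_values"],
                        k=header["k"], d=header["d"], seed=header["seed"])
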