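import numpy as np
import pytest

from rtname import synthetic
from rtname.datatypes import ImageSeries


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def prostate_phantom():
    """One deterministic prostate phantom (series + structure set)."""
    rng = np.random.default_rng(42)
    cfg = synthetic.CohortConfig(disease="prostate", other_structures_range=(2, 4), seed=42)
    return synthetic.generate_phantom("prostate", "P000", rng, cfg)


@pytest.fixture()
def small_series():
    """Tiny 8x8x6 series with 1 mm in-plane and 2 mm slice spacing."""
    voxels = np.zeros((6, 8, 8), dtype=np.int16)
    z = np.arange(6) * 2.0
    return ImageSeries(voxels=voxels, origin=np.zeros(3), spacing=np.array([1.0, 1.0, 2.0]),
                       orientation=np.eye(3), slice_positions=z, patient_id="T1")


def make_series(nx=8, ny=8, nz=6, spacing=(1.0, 1.0, 2.0), origin=(0.0, 0.0, 0.0),
                voxels=None, patient_id="T"):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if voxels is None:
        voxels = np.zeros((nz, ny, nx), dtype=np.int16)
    z = origin[2] + np.arange(voxels.shape[0]) * spacing[2]
    return ImageSeries(voxels=voxels, origin=origin, spacing=spacing,
                       orientation=np.eye(3), slice_positions=z, patient_id=patient_id)
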