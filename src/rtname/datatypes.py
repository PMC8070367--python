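"""Shared data model for radiotherapy structure-set processing.

All spatial quantities are expressed in the DICOM patient coordinate
system (LPS: +x patient-left, +y posterior, +z superior), in millimetres.
Only axial series (identity orientation) are supported; oblique series are
rejected at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSeries",
    "Contour",
    "StructureRecord",
    "StructureSet",
    "BoundingBox",
    "BinaryVolume",
    "LabelSet",
    "PROSTATE_LABELS",
    "LUNG_LABELS",
    "OTHER_LABEL",
    "DEFAULT_GRID_SHAPE",
    "labelset_for",
]

#: Target occupancy-grid shape (nx, ny, nz) for geometric featurization.
DEFAULT_GRID_SHAPE = (96, 96, 48)

OTHER_LABEL = "other"


@dataclass
class ImageSeries:
    """A 3D CT grid in Hounsfield Units with patient-space geometry.

    ``voxels`` is indexed ``[k, j, i]`` = (slice, row, column), the natural
    stacking order of a DICOM series; ``origin`` is the patient-space
    position of the centre of voxel ``[0, 0, 0]`` and ``spacing`` is
    ``(dx, dy, dz)`` mm per voxel along (column, row, slice).
    """

    voxels: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    orientation: np.ndarray
    slice_positions: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D grid")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        dz = np.diff(self.slice_positions)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("slice_positions must be strictly monotonic")

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        """Grid extent as (nx, ny, nz)."""
        nz, ny, nx = self.voxels.shape
        return nx, ny, nz


@dataclass
class Contour:
    """One closed planar polygon of a delineated structure.

    ``points`` is an (n, 2) array of (x, y) patient coordinates in mm on the
    axial plane at ``slice_z``; closure is implicit (the first point is not
    repeated at the end).
    """

    slice_z: float
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class StructureRecord:
    """One delineated structure: the verbatim physician-given name, its
    per-slice contours, and (when known) the ground-truth standard label.

    ``given_name`` is preserved byte-for-byte at read time — lowercasing or
    any other normalisation is an explicit, separate step.
    """

    given_name: str
    contours: list[Contour] = field(default_factory=list)
    true_label: str | None = None
    patient_id: str = ""
    center_id: str = ""


@dataclass
class StructureSet:
    """All structures delineated for one patient's plan."""

    records: list[StructureRecord]
    patient_id: str = ""

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.patient_id and self.patient_id and rec.patient_id != self.patient_id:
                raise ValueError("all records must reference the structure set's patient")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BoundingBox:
    """Axis-aligned patient-space box, mm."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=float)
        self.max_corner = np.asarray(self.max_corner, dtype=float)
        if not np.all(self.max_corner > self.min_corner):
            raise ValueError("max_corner must exceed min_corner componentwise")

    @property
    def size(self) -> np.ndarray:
        return self.max_corner - self.min_corner


@dataclass
class BinaryVolume:
    """Fixed-shape {0,1} occupancy grid spanning a bounding box.

    ``bits`` is indexed ``[i, j, k]`` = (x, y, z) cell indices.
    """

    bits: np.ndarray
    box: BoundingBox

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 3:
            raise ValueError("bits must be 3D")
        vals = np.unique(self.bits)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("bits must contain only 0/1")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.bits.shape)


@dataclass(frozen=True)
class LabelSet:
    """Ordered set of standard class names for one disease site.

    The order is fixed at task creation: it defines probability-vector and
    confusion-matrix layout and breaks argmax ties deterministically.
    """

    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if OTHER_LABEL not in self.class_names:
            raise ValueError(f"labelset must contain {OTHER_LABEL!r}")

    def __len__(self) -> int:
        return len(self.class_names)

    def __iter__(self):
        return iter(self.class_names)

    def index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown label {name!r}") from None


# TG-263 targets for the two disease sites, OARs + PTV + catch-all "other".
PROSTATE_LABELS = LabelSet(
    ("Femur_L", "Femur_R", "Bowel_Large", "Bowel_Small", "Bladder", "Rectum", "PTV", OTHER_LABEL)
)
LUNG_LABELS = LabelSet(
    ("Esophagus", "SpinalCord", "Brachial_Plexus", "Heart", "PTV", OTHER_LABEL)
)


def labelset_for(disease: str) -> LabelSet:
    if disease == "prostate":
        return PROSTATE_LABELS
    if disease == "lung":
        return LUNG_LABELS
    raise ValueError(f"unknown disease {disease!r} (expected 'prostate' or 'lung')")
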