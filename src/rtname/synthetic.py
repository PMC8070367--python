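"""Synthetic multi-center cohorts: CT phantoms plus aliased structure names.

The generator emulates the statistical structure of multi-institutional
radiotherapy structure-set data:

* per-center naming conventions — each center fixes one preferred alias
  per standard class (drawn from a table of clinically observed aliases),
  with per-structure noise (case flips, alias swaps, generic suffixes);
* cross-center label ambiguity — a configurable fraction of centers uses
  the bare alias "bowel", some meaning the small bowel and others the
  large bowel, so a text-only model trained across centers necessarily
  confuses the two while the geometry view can separate them (the two
  bowel classes are generated at distinct locations by construction);
* severe class imbalance — every patient carries many unlabeled "other"
  structures (markers, couch parts, optimisation volumes, ...) so that
  "other" is the modal class, as in real plans;
* anatomically plausible geometry — a soft-tissue body column in an air
  background with high-HU bony landmarks (vertebral column, and femoral
  heads for the pelvis), and one ellipsoidal structure per OAR/PTV class
  at class-specific jittered locations.

Phantoms use a 96 x 96 x 48 voxel grid at 4 x 4 x 5 mm spacing (body-scale
extent, seconds-per-patient generation). All randomness flows from one
seed through named substreams (geometry / naming / cohort layout), so any
part of a cohort can be regenerated stably.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Contour, ImageSeries, StructureRecord, StructureSet, labelset_for, OTHER_LABEL
from . import dicom_io

__all__ = [
    "CohortConfig",
    "CenterProfile",
    "ALIAS_TABLES",
    "OTHER_NAME_POOL",
    "generate_phantom",
    "sample_name",
    "make_center_profiles",
    "generate_cohort_records",
    "generate_cohort",
]

# Aliases observed in clinical naming practice for each standard class.
# The bare "bowel" alias is deliberately excluded here: it is introduced
# only by ambiguous centers (see CenterProfile), where its meaning depends
# on the center's convention.
ALIAS_TABLES: dict[str, dict[str, list[str]]] = {
    "prostate": {
        "Femur_L": ["LtFemoral Head", "Left Fem", "Fem hdneck Lt"],
        "Femur_R": ["Fem Rt", "Rt_Fem", "Femoral_Rt"],
        "Bladder": ["bldr", "bladder-KS", "BLADDER"],
        "Bowel_Small": ["SM_bowel", "small bowel", "sbowel"],
        "Bowel_Large": ["bowel_lg", "colon", "lg bowel"],
        "Rectum": ["Rectum", "Rect", "rectum"],
        "PTV": ["PTV_Prost", "PTV", "ptv 79.2"],
    },
    "lung": {
        "Esophagus": ["esophagus", "Esoph", "ESOPHAGUS"],
        "SpinalCord": ["cord", "Spinal Cord", "SpinalCord"],
        "Brachial_Plexus": ["Brachial Plexus", "brach_plex", "BP"],
        "Heart": ["heart", "HEART", "Heart"],
        "PTV": ["PTV_Lung", "PTV", "ptv 60"],
    },
}

# Names for planning-related / miscellaneous structures.
OTHER_NAME_POOL = [
    "Rectum subptv", "Dose 107.1[%]", "RFH", "Prostate", "PTV79.2", "Balloon",
    "PTV45", "CTV45_OPT", "CouchSurface", "ProxSV", "Pelvic Nodes", "Rec50",
    "CTV vessels", "Marker1", "POST", "BLDSPARE", "PROS+SV'S", "out", "70opti",
    "Blad_NO_ptv", "External", "dosavoid2", "calcification", "Marker3",
    "FIDUCIALS", "bulb", "Seeds", "CouchInterior", "PTV_NDS", "CTV", "ROI_1",
]

# Ellipsoid priors per class: patient-space centre (mm, LPS) and half-axes.
_ORGAN_PRIORS: dict[str, dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]] = {
    "prostate": {
        "Femur_L": ((95.0, 10.0, -40.0), (22.0, 22.0, 45.0)),
        "Femur_R": ((-95.0, 10.0, -40.0), (22.0, 22.0, 45.0)),
        "Bladder": ((0.0, -30.0, -10.0), (35.0, 28.0, 22.0)),
        "Rectum": ((0.0, 55.0, -25.0), (16.0, 16.0, 45.0)),
        "PTV": ((0.0, 10.0, -20.0), (30.0, 26.0, 24.0)),
        "Bowel_Small": ((15.0, -20.0, 55.0), (45.0, 35.0, 28.0)),
        "Bowel_Large": ((-50.0, 25.0, 40.0), (30.0, 25.0, 32.0)),
    },
    "lung": {
        "Esophagus": ((0.0, 25.0, 10.0), (9.0, 9.0, 80.0)),
        "SpinalCord": ((0.0, 70.0, 0.0), (7.0, 7.0, 110.0)),
        "Brachial_Plexus": ((25.0, 40.0, 85.0), (18.0, 10.0, 14.0)),
        "Heart": ((25.0, -10.0, -30.0), (50.0, 40.0, 40.0)),
        "PTV": ((-60.0, -10.0, 20.0), (28.0, 28.0, 30.0)),
    },
}

_GRID = (96, 96, 48)           # phantom voxels (nx, ny, nz)
_SPACING = (4.0, 4.0, 5.0)     # mm
_AIR_HU, _SOFT_HU, _BONE_HU = -1000, 0, 1500
_BODY_HALF_AXES = (165.0, 130.0)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    disease: str = "prostate"
    n_centers: int = 40
    patients_per_center: int = 5
    other_structures_range: tuple[int, int] = (15, 24)
    ambiguity_rate: float = 0.5
    case_flip_prob: float = 0.10
    alias_swap_prob: float = 0.10
    suffix_prob: float = 0.05
    geometry_jitter_mm: float = 8.0
    size_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.ambiguity_rate, self.case_flip_prob, self.alias_swap_prob, self.suffix_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_centers < 1 or self.patients_per_center < 1:
            raise ValueError("counts must be >= 1")
        labelset_for(self.disease)  # validates the disease tag


@dataclass
class CenterProfile:
    """One center's fixed naming convention."""

    center_id: str
    preferred_alias: dict[str, str]
    ambiguous: bool = False
    bowel_convention: str | None = None  # "Bowel_Small" or "Bowel_Large"


def _substream(seed: int, *keys: str) -> np.random.Generator:
    digest = hashlib.sha256(("|".join(map(str, keys))).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *words])


def _grid_coords() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = _GRID
    dx, dy, dz = _SPACING
    origin = np.array([-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz])
    xs = origin[0] + np.arange(nx) * dx
    ys = origin[1] + np.arange(ny) * dy
    zs = origin[2] + np.arange(nz) * dz
    return origin, xs, ys, zs, np.array([dx, dy, dz])


def _ellipsoid_contours(center, axes, slice_zs, n_vertices: int = 32) -> list[Contour]:
    cx, cy, cz = center
    ax, ay, az = axes
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    contours = []
    for z in slice_zs:
        u = (z - cz) / az
        if abs(u) >= 1.0:
            continue
        scale = float(np.sqrt(1.0 - u * u))
        if scale < 0.12:
            continue
        pts = np.column_stack([cx + ax * scale * np.cos(theta),
                               cy + ay * scale * np.sin(theta)])
        contours.append(Contour(slice_z=float(z), points=pts))
    return contours


def _box_contours(center, half_sizes, slice_zs) -> list[Contour]:
    cx, cy, cz = center
    hx, hy, hz = half_sizes
    contours = []
    for z in slice_zs:
        if abs(z - cz) > hz:
            continue
        pts = np.array([[cx - hx, cy - hy], [cx + hx, cy - hy],
                        [cx + hx, cy + hy], [cx - hx, cy + hy]])
        contours.append(Contour(slice_z=float(z), points=pts))
    return contours


def generate_phantom(disease: str, patient_id: str, rng: np.random.Generator,
                     config: CohortConfig | None = None) -> tuple[ImageSeries, StructureSet]:
    """One patient: HU phantom plus a contoured structure set.

    The structure set carries one record per OAR/PTV class (given_name
    initialised to the true label; cohort generation replaces it with a
    center-specific alias) plus a configurable number of "other"
    structures at random positions inside the body.
    """
    cfg = config or CohortConfig(disease=disease)
    labelset = labelset_for(disease)
    origin, xs, ys, zs, spacing = _grid_coords()
    nx, ny, nz = _GRID

    X = xs[None, None, :]      # voxels indexed [k(z), j(y), i(x)]
    Y = ys[None, :, None]
    Z = zs[:, None, None]

    hu = np.full((nz, ny, nx), _AIR_HU, dtype=np.int16)
    body = (X / _BODY_HALF_AXES[0]) ** 2 + (Y / _BODY_HALF_AXES[1]) ** 2 <= 1.0
    hu[np.broadcast_to(body, hu.shape)] = _SOFT_HU

    # bony landmarks: vertebral column, plus femoral heads for the pelvis
    vert = ((X - 0.0) / 14.0) ** 2 + ((Y - 80.0) / 14.0) ** 2 <= 1.0
    hu[np.broadcast_to(vert, hu.shape)] = _BONE_HU
    if disease == "prostate":
        for sx, (cx, cy, cz) in (("L", (95.0, 10.0, -40.0)), ("R", (-95.0, 10.0, -40.0))):
            sphere = ((X - cx) / 20.0) ** 2 + ((Y - cy) / 20.0) ** 2 + ((Z - cz) / 20.0) ** 2 <= 1.0
            hu[sphere] = _BONE_HU
    noise = rng.normal(0.0, 15.0, size=hu.shape)
    hu = (hu + np.rint(noise)).astype(np.int16)

    records = []
    for cls, (c_mean, a_mean) in _ORGAN_PRIORS[disease].items():
        center = np.asarray(c_mean) + rng.normal(0.0, cfg.geometry_jitter_mm, size=3)
        axes = np.asarray(a_mean) * rng.uniform(1.0 - cfg.size_jitter, 1.0 + cfg.size_jitter, size=3)
        contours = _ellipsoid_contours(center, axes, zs)
        records.append(StructureRecord(given_name=cls, contours=contours,
                                       true_label=cls, patient_id=patient_id))

    n_other = int(rng.integers(cfg.other_structures_range[0], cfg.other_structures_range[1] + 1))
    for _ in range(n_other):
        center = np.array([rng.uniform(-120, 120), rng.uniform(-100, 100), rng.uniform(-100, 100)])
        half = rng.uniform(6.0, 45.0, size=3)
        if rng.random() < 0.5:
            contours = _ellipsoid_contours(center, half, zs)
        else:
            contours = _box_contours(center, half, zs)
        records.append(StructureRecord(given_name=OTHER_LABEL, contours=contours,
                                       true_label=OTHER_LABEL, patient_id=patient_id))

    series = ImageSeries(voxels=hu, origin=origin, spacing=spacing,
                         orientation=np.eye(3), slice_positions=zs, patient_id=patient_id)
    assert labelset  # all priors are members of the task labelset
    return series, StructureSet(records=records, patient_id=patient_id)


def make_center_profiles(config: CohortConfig) -> list[CenterProfile]:
    """Fix each center's preferred alias per class and, for ambiguous
    centers, which bowel class the bare alias "bowel" refers to."""
    rng = _substream(config.seed, "centers")
    aliases = ALIAS_TABLES[config.disease]
    n_ambiguous = int(round(config.ambiguity_rate * config.n_centers))
    ambiguous = set(rng.choice(config.n_centers, size=n_ambiguous, replace=False).tolist())
    profiles = []
    for c in range(config.n_centers):
        center_id = f"C{c:02d}"
        preferred = {cls: str(rng.choice(opts)) for cls, opts in aliases.items()}
        is_amb = c in ambiguous and config.disease == "prostate"
        convention = None
        if is_amb:
            convention = "Bowel_Small" if rng.random() < 0.5 else "Bowel_Large"
            preferred[convention] = "bowel"
        profiles.append(CenterProfile(center_id=center_id, preferred_alias=preferred,
                                      ambiguous=is_amb, bowel_convention=convention))
    return profiles


_SUFFIXES = ["_1", "_2", " copy", "_old"]


def sample_name(cls: str, profile: CenterProfile, rng: np.random.Generator,
                config: CohortConfig) -> str:
    """Draw the physician-given name for one structure instance.

    The center's preferred alias for the class, optionally perturbed by
    alias swap, case flip, and a generic suffix. "other" structures draw
    from a pool of planning-related names plus ROI_<n> templates.
    """
    if cls == OTHER_LABEL:
        if rng.random() < 0.25:
            return f"ROI_{int(rng.integers(1, 40))}"
        return str(rng.choice(OTHER_NAME_POOL))
    aliases = ALIAS_TABLES[config.disease]
    if cls not in aliases:
        raise KeyError(f"unknown class {cls!r}")
    name = profile.preferred_alias[cls]
    swap_allowed = not (profile.ambiguous and cls == profile.bowel_convention)
    if swap_allowed and rng.random() < config.alias_swap_prob:
        name = str(rng.choice(aliases[cls]))
    if rng.random() < config.case_flip_prob:
        name = name.upper() if rng.random() < 0.5 else name.lower()
    if rng.random() < config.suffix_prob:
        name = name + _SUFFIXES[int(rng.integers(len(_SUFFIXES)))]
    return name


def generate_cohort_records(config: CohortConfig):
    """In-memory cohort: yields (center_id, patient_id, series, sset)
    with center-specific given names and a deterministic layout."""
    profiles = make_center_profiles(config)
    out = []
    for profile in profiles:
        for p in range(config.patients_per_center):
            patient_id = f"{profile.center_id}_P{p:02d}"
            geo_rng = _substream(config.seed, "geometry", patient_id)
            name_rng = _substream(config.seed, "naming", patient_id)
            series, sset = generate_phantom(config.disease, patient_id, geo_rng, config)
            for rec in sset.records:
                rec.center_id = profile.center_id
                rec.given_name = sample_name(rec.true_label, profile, name_rng, config)
            out.append((profile.center_id, patient_id, series, sset))
    return out


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort to disk as DICOM (one directory per patient) plus a
    labels manifest CSV; returns the manifest. Byte-identical across runs
    with the same config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for center_id, patient_id, series, sset in generate_cohort_records(config):
        pdir = out_dir / patient_id
        dicom_io.write_synthetic_dicom(series, sset, pdir)
        for s, rec in enumerate(sset.records):
            rows.append({
                "patient_id": patient_id,
                "center_id": center_id,
                "structure_id": f"{patient_id}_S{s:03d}",
                "given_name": rec.given_name,
                "true_label": rec.true_label,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    return manifest
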