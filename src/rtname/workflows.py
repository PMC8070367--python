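"""End-to-end orchestration: cohort featurization, bundle training,
per-mode evaluation, and the multi-center benchmark.

The benchmark mirrors the study design the package exists for: generate a
multi-center cohort, hold out whole centers, train the text-only,
image-only, intermediate-integration and late-integration models on the
training centers, and compare their macro metrics (plus the
majority-label baseline) on the held-out centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ImageSeries, StructureRecord, LabelSet, labelset_for, DEFAULT_GRID_SHAPE
from . import dim_reduce, evaluate, integrate, synthetic, text_features, voxelize

__all__ = ["Cohort", "FeaturizedCohort", "featurize_cohort", "train_bundle",
           "predict_modes", "run_benchmark", "BenchmarkResult"]

#: SVD ranks used by the two integration branches.
SVD_K_INTERMEDIATE = 50
SVD_K_LATE = 100


@dataclass
class Cohort:
    """In-memory cohort: per-patient series/structure-set plus a flat
    record table aligned with the feature matrix rows."""

    disease: str
    patients: list[tuple[str, str, ImageSeries, object]]  # center, patient, series, sset

    @property
    def labelset(self) -> LabelSet:
        return labelset_for(self.disease)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for center_id, patient_id, _, sset in self.patients:
            for s, rec in enumerate(sset.records):
                rows.append({"patient_id": patient_id, "center_id": center_id,
                             "structure_id": f"{patient_id}_S{s:03d}",
                             "given_name": rec.given_name, "true_label": rec.true_label})
        return pd.DataFrame(rows)

    def iter_records(self):
        for center_id, patient_id, series, sset in self.patients:
            for rec in sset.records:
                yield center_id, patient_id, series, rec


def generate_synthetic_cohort(config: synthetic.CohortConfig) -> Cohort:
    return Cohort(disease=config.disease,
                  patients=synthetic.generate_cohort_records(config))


@dataclass
class FeaturizedCohort:
    """Geometry matrix (sparse, one {0,1} row per structure) plus the
    aligned names/labels/centers arrays."""

    geometry: sp.csr_matrix
    names: list[str]
    labels: list[str]
    centers: np.ndarray
    patients: np.ndarray
    records: list[StructureRecord]
    series_by_row: list[ImageSeries]
    grid_shape: tuple[int, int, int]
    include_bone: bool


def featurize_cohort(cohort: Cohort, grid_shape=DEFAULT_GRID_SHAPE,
                     include_bone: bool = False) -> FeaturizedCohort:
    """Rasterize every structure onto its patient's image bounding box and
    assemble the sparse geometric feature matrix."""
    data_indices, indptr = [], [0]
    names, labels, centers, patients, records, series_by_row = [], [], [], [], [], []
    d = int(np.prod(grid_shape)) * (2 if include_bone else 1)
    for center_id, patient_id, series, sset in cohort.patients:
        box = voxelize.compute_bounding_box(series)
        bone_vec = None
        if include_bone:
            bone_vec = voxelize.flatten(voxelize.extract_bony_anatomy(series, box, grid_shape))
        for rec in sset.records:
            vec = voxelize.flatten(voxelize.rasterize_structure(rec, box, grid_shape))
            if include_bone:
                vec = voxelize.concat_structure_and_bone(vec, bone_vec)
            nz = np.flatnonzero(vec)
            data_indices.append(nz)
            indptr.append(indptr[-1] + len(nz))
            names.append(text_features.preprocess_name(rec.given_name))
            labels.append(rec.true_label)
            centers.append(center_id)
            patients.append(patient_id)
            records.append(rec)
            series_by_row.append(series)
    indices = np.concatenate(data_indices) if data_indices else np.empty(0, dtype=int)
    geometry = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.float32), indices, np.asarray(indptr)),
        shape=(len(names), d),
    )
    return FeaturizedCohort(geometry=geometry, names=names, labels=labels,
                            centers=np.asarray(centers), patients=np.asarray(patients),
                            records=records, series_by_row=series_by_row,
                            grid_shape=tuple(grid_shape), include_bone=include_bone)


def train_bundle(feat: FeaturizedCohort, train_mask: np.ndarray, labelset: LabelSet,
                 seed: int = 0, text_config: text_features.TextConfig | None = None,
                 svd_k_intermediate: int = SVD_K_INTERMEDIATE,
                 svd_k_late: int = SVD_K_LATE) -> integrate.PipelineBundle:
    """Train every branch on the rows selected by ``train_mask``.

    One SVD is fit at the larger rank and truncated for the intermediate
    branch (the leading components of the same decomposition).
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    names = [n for n, m in zip(feat.names, train_mask) if m]
    labels = [l for l, m in zip(feat.labels, train_mask) if m]
    geom_train = feat.geometry[train_mask]

    cfg = text_config or text_features.TextConfig(seed=seed)
    text_model = text_features.train_text_model(names, labels, cfg,
                                                class_names=labelset.class_names)

    k_max = max(svd_k_late, svd_k_intermediate)
    svd_full = dim_reduce.fit_truncated_svd(geom_train, k=k_max, seed=seed)
    svd_late = dim_reduce.truncate(svd_full, svd_k_late)
    svd_inter = dim_reduce.truncate(svd_full, svd_k_intermediate)

    reduced_late = dim_reduce.transform(svd_late, geom_train)
    image_clf = integrate.train_classifier(reduced_late, labels, labelset, seed=seed)

    docs = np.vstack([text_features.embed_name(text_model, n) for n in names])
    reduced_inter = dim_reduce.transform(svd_inter, geom_train)
    inter_features = np.hstack([docs, reduced_inter])
    inter_clf = integrate.train_classifier(inter_features, labels, labelset, seed=seed)

    return integrate.PipelineBundle(
        labelset=labelset, grid_shape=feat.grid_shape, include_bone=feat.include_bone,
        text_model=text_model, svd_image=svd_late, svd_intermediate=svd_inter,
        image_classifier=image_clf, intermediate_classifier=inter_clf,
    )


def predict_modes(bundle: integrate.PipelineBundle, feat: FeaturizedCohort,
                  mask: np.ndarray, modes=integrate.MODES) -> dict[str, list[str]]:
    """Batch predictions for the selected rows, per mode (vectorised over
    the already-featurized geometry rather than re-rasterizing)."""
    mask = np.asarray(mask, dtype=bool)
    names = [n for n, m in zip(feat.names, mask) if m]
    geom = feat.geometry[mask]
    labelset = bundle.labelset

    text_probs = np.vstack([text_features.predict_text_proba(bundle.text_model, n)
                            for n in names]) if bundle.text_model else None
    image_probs = None
    if bundle.image_classifier is not None:
        reduced = dim_reduce.transform(bundle.svd_image, geom)
        image_probs = bundle.image_classifier.predict_proba(reduced)

    out: dict[str, list[str]] = {}
    for mode in modes:
        if mode == "text":
            idx = text_probs.argmax(axis=1)
        elif mode == "image":
            idx = image_probs.argmax(axis=1)
        elif mode == "intermediate":
            docs = np.vstack([text_features.embed_name(bundle.text_model, n) for n in names])
            reduced_i = dim_reduce.transform(bundle.svd_intermediate, geom)
            probs = bundle.intermediate_classifier.predict_proba(np.hstack([docs, reduced_i]))
            idx = probs.argmax(axis=1)
        elif mode == "late_avg":
            idx = ((text_probs + image_probs) / 2.0).argmax(axis=1)
        elif mode == "late_max":
            idx = np.maximum(text_probs, image_probs).argmax(axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out[mode] = [labelset.class_names[i] for i in idx]
    return out


@dataclass
class BenchmarkResult:
    reports: dict[str, evaluate.EvaluationReport]
    confusions: dict[str, evaluate.ConfusionMatrix]
    test_centers: list[str]
    manifest: pd.DataFrame
    truth: list[str] = field(default_factory=list)
    predictions: dict[str, list[str]] = field(default_factory=dict)


def run_benchmark(config: synthetic.CohortConfig, n_test_centers: int = 10,
                  seed: int | None = None, include_bone: bool = False,
                  grid_shape=DEFAULT_GRID_SHAPE) -> BenchmarkResult:
    """Generate a cohort, hold out whole centers, train all branches, and
    evaluate every mode plus the majority-label baseline on the holdout."""
    seed = config.seed if seed is None else seed
    cohort = generate_synthetic_cohort(config)
    labelset = cohort.labelset
    feat = featurize_cohort(cohort, grid_shape=grid_shape, include_bone=include_bone)

    row_ids = np.arange(len(feat.names))
    plan = evaluate.center_holdout(row_ids, feat.centers, n_test_centers, seed=seed)
    split = plan.splits[0]
    train_mask = np.zeros(len(row_ids), dtype=bool)
    train_mask[np.asarray(split["train"], dtype=int)] = True
    test_mask = ~train_mask

    bundle = train_bundle(feat, train_mask, labelset, seed=seed)
    preds = predict_modes(bundle, feat, test_mask)

    truth = [l for l, m in zip(feat.labels, test_mask) if m]
    train_labels = [l for l, m in zip(feat.labels, train_mask) if m]
    mlb = evaluate.majority_label_baseline(train_labels, labelset)
    preds["mlb"] = mlb.predict(truth)

    reports, confusions = {}, {}
    for mode, p in preds.items():
        cm = evaluate.confusion(truth, p, labelset)
        confusions[mode] = cm
        reports[mode] = evaluate.compute_metrics(cm)
    return BenchmarkResult(reports=reports, confusions=confusions,
                           test_centers=[str(c) for c in split["test_centers"]],
                           manifest=cohort.manifest(), truth=truth, predictions=preds)
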