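"""Multi-view combiners for structure-name classification.

Four ways of using the two views (text = physician-given name, image =
structure geometry):

* single-view text: subword-embedding softmax classifier;
* single-view image: truncated-SVD features (k=100 by default) into a
  random-forest classifier;
* intermediate integration: the 200-dim document vector concatenated with
  the k=50 reduced geometry vector (250 features) into one random forest;
* late integration: the per-view class-probability vectors fused at
  prediction time, element-wise average (AVG) or element-wise maximum
  (MAX, not renormalized — renormalization cannot change the argmax).

Argmax ties always break by labelset order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datatypes import BoundingBox, ImageSeries, LabelSet, StructureRecord
from . import dim_reduce, text_features, voxelize

__all__ = [
    "build_intermediate_feature",
    "EnsembleClassifier",
    "train_classifier",
    "fuse_avg",
    "fuse_max",
    "predict_late",
    "PipelineBundle",
    "predict_pipeline",
    "MODES",
]

MODES = ("text", "image", "intermediate", "late_avg", "late_max")


def build_intermediate_feature(doc: np.ndarray, reduced: np.ndarray) -> np.ndarray:
    """Concatenate the text document vector with the reduced geometry
    vector (document entries first)."""
    doc = np.asarray(doc, dtype=np.float64).ravel()
    reduced = np.asarray(reduced, dtype=np.float64).ravel()
    if not (np.all(np.isfinite(doc)) and np.all(np.isfinite(reduced))):
        raise ValueError("non-finite entries in view features")
    return np.concatenate([doc, reduced])


@dataclass
class EnsembleClassifier:
    """Random-forest ensemble whose probability output is aligned to a
    fixed labelset order (classes absent from training get probability 0)."""

    forest: RandomForestClassifier
    labelset: LabelSet
    trained_classes: tuple[str, ...] = field(default=())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        raw = self.forest.predict_proba(X)
        out = np.zeros((len(X), len(self.labelset)))
        for col, cls_idx in enumerate(self.forest.classes_):
            out[:, int(cls_idx)] = raw[:, col]
        return out

    def predict(self, X: np.ndarray) -> list[str]:
        proba = self.predict_proba(X)
        return [self.labelset.class_names[i] for i in proba.argmax(axis=1)]


def train_classifier(features: np.ndarray, labels, labelset: LabelSet,
                     n_estimators: int = 100, max_depth: int | None = None,
                     seed: int = 0) -> EnsembleClassifier:
    """Fit the randomized-tree ensemble; deterministic given seed."""
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("degenerate task: need >= 2 classes in training labels")
    y = np.asarray([labelset.index(l) for l in labels])
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        max_features="sqrt", random_state=seed, n_jobs=1,
    )
    forest.fit(np.asarray(features, dtype=np.float64), y)
    return EnsembleClassifier(forest=forest, labelset=labelset,
                              trained_classes=tuple(sorted(set(labels))))


def _check_views(view_probs) -> np.ndarray:
    probs = [np.asarray(p, dtype=np.float64).ravel() for p in view_probs]
    if not probs:
        raise ValueError("need at least one view")
    n = len(probs[0])
    for p in probs:
        if len(p) != n:
            raise ValueError("probability vectors must have equal length and label order")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("view probabilities must be valid distributions")
    return np.vstack(probs)


def fuse_avg(view_probs) -> np.ndarray:
    """Element-wise mean of the per-view probability vectors."""
    return _check_views(view_probs).mean(axis=0)


def fuse_max(view_probs, labelset: LabelSet | None = None):
    """Element-wise maximum across views (raw, not renormalized) and the
    argmax class; ties break by labelset order."""
    scores = _check_views(view_probs).max(axis=0)
    idx = int(scores.argmax())  # argmax returns the first maximum = labelset order
    name = labelset.class_names[idx] if labelset is not None else idx
    return scores, name


def predict_late(text_probs, image_probs, method: str, labelset: LabelSet) -> str:
    """Final class from late fusion of the two single-view posteriors."""
    if method == "avg":
        fused = fuse_avg([text_probs, image_probs])
        return labelset.class_names[int(fused.argmax())]
    if method == "max":
        _, name = fuse_max([text_probs, image_probs], labelset)
        return name
    raise ValueError(f"unknown late-fusion method {method!r} (expected 'avg' or 'max')")


@dataclass
class PipelineBundle:
    """All trained artifacts needed to classify a structure record."""

    labelset: LabelSet
    grid_shape: tuple[int, int, int]
    include_bone: bool = False
    text_model: text_features.TextModel | None = None
    svd_image: dim_reduce.SvdModel | None = None           # late / single-view branch
    svd_intermediate: dim_reduce.SvdModel | None = None    # inside intermediate integration
    image_classifier: EnsembleClassifier | None = None
    intermediate_classifier: EnsembleClassifier | None = None


def _geometry_vector(record: StructureRecord, series: ImageSeries,
                     bundle: PipelineBundle) -> np.ndarray:
    box = voxelize.compute_bounding_box(series)
    vec = voxelize.flatten(voxelize.rasterize_structure(record, box, bundle.grid_shape))
    if bundle.include_bone:
        bone = voxelize.flatten(voxelize.extract_bony_anatomy(series, box, bundle.grid_shape))
        vec = voxelize.concat_structure_and_bone(vec, bone)
    return vec


def _require(bundle: PipelineBundle, mode: str, **artifacts):
    for name, value in artifacts.items():
        if value is None:
            raise ValueError(f"mode {mode!r} requires a trained {name}")


def predict_pipeline(record: StructureRecord, series: ImageSeries,
                     bundle: PipelineBundle, mode: str) -> tuple[str, np.ndarray]:
    """End-to-end prediction for one structure.

    Composes preprocess -> embed (text view) and rasterize -> reduce ->
    classify (image view), then fuses according to ``mode``. Returns the
    predicted class and the probability (or fused score) vector.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r} (expected one of {MODES})")
    labelset = bundle.labelset
    name = text_features.preprocess_name(record.given_name)

    if mode == "text":
        _require(bundle, mode, text_model=bundle.text_model)
        probs = text_features.predict_text_proba(bundle.text_model, name)
        return labelset.class_names[int(probs.argmax())], probs

    if mode == "image":
        _require(bundle, mode, svd_image=bundle.svd_image,
                 image_classifier=bundle.image_classifier)
        reduced = dim_reduce.transform(bundle.svd_image, _geometry_vector(record, series, bundle))
        probs = bundle.image_classifier.predict_proba(reduced)[0]
        return labelset.class_names[int(probs.argmax())], probs

    if mode == "intermediate":
        _require(bundle, mode, text_model=bundle.text_model,
                 svd_intermediate=bundle.svd_intermediate,
                 intermediate_classifier=bundle.intermediate_classifier)
        doc = text_features.embed_name(bundle.text_model, name)
        reduced = dim_reduce.transform(bundle.svd_intermediate,
                                       _geometry_vector(record, series, bundle))
        feat = build_intermediate_feature(doc, reduced)
        probs = bundle.intermediate_classifier.predict_proba(feat)[0]
        return labelset.class_names[int(probs.argmax())], probs

    # late fusion
    _require(bundle, mode, text_model=bundle.text_model, svd_image=bundle.svd_image,
             image_classifier=bundle.image_classifier)
    text_probs = text_features.predict_text_proba(bundle.text_model, name)
    reduced = dim_reduce.transform(bundle.svd_image, _geometry_vector(record, series, bundle))
    image_probs = bundle.image_classifier.predict_proba(reduced)[0]
    if mode == "late_avg":
        fused = fuse_avg([text_probs, image_probs])
    else:
        fused, _ = fuse_max([text_probs, image_probs], labelset)
    return labelset.class_names[int(fused.argmax())], fused
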