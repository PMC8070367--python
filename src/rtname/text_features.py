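"""Supervised character n-gram embedding classifier for structure names.

Physician-given structure names are short, heavily abbreviated strings
("bldr", "Fem hdneck Lt", "PTV_Prost"), so subword features carry most of
the signal. The model here is the classic supervised bag-of-subwords
architecture: each whitespace token is wrapped in boundary markers
("<bldr>"), decomposed into character n-grams plus the whole wrapped
token, each n-gram is hashed into a bucket with its own embedding row, a
name is represented as the mean of its n-gram embeddings, and a linear
softmax layer on top is trained by SGD on cross-entropy with a linearly
decaying learning rate.

Preprocessing is deliberately minimal — lowercasing only — because the
character set of clinical names is already small and aggressive
normalisation would destroy discriminative detail.

Defaults (character n-grams 2-5, embedding dim 200, 2^20 hash buckets,
25 epochs, initial lr 0.5) follow standard practice for short-text
supervised embedding models. Training is pure NumPy, single-threaded and
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "preprocess_name",
    "extract_char_ngrams",
    "TextConfig",
    "TextModel",
    "train_text_model",
    "embed_name",
    "predict_text_proba",
    "save_text_model",
    "load_text_model",
]


def preprocess_name(raw: str) -> str:
    """Lowercase the physician-given name; no other mutation."""
    return raw.lower()


def extract_char_ngrams(name: str, n_min: int = 2, n_max: int = 5) -> list[str]:
    """Character n-grams of each whitespace token wrapped in '<'/'>'
    boundary markers, plus the whole wrapped token itself."""
    if not (1 <= n_min <= n_max):
        raise ValueError("require 1 <= n_min <= n_max")
    grams: list[str] = []
    for token in name.split():
        wrapped = f"<{token}>"
        for n in range(n_min, n_max + 1):
            grams.extend(wrapped[i:i + n] for i in range(len(wrapped) - n + 1))
        grams.append(wrapped)
    return grams


def _fnv1a64(s: str) -> int:
    h = 0xCBF29CE484222325
    for b in s.encode("utf-8"):
        h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


@dataclass
class TextConfig:
    dim: int = 200
    n_min: int = 2
    n_max: int = 5
    buckets: int = 2 ** 20
    epochs: int = 25
    lr: float = 0.5
    seed: int = 0


@dataclass
class TextModel:
    """Trained name classifier.

    ``ngram_table`` maps hashed n-gram ids to rows of ``embeddings``; only
    n-grams seen at training time have a row (an unseen n-gram simply
    contributes nothing, and a fully out-of-vocabulary name embeds to the
    zero vector, which the softmax maps to the uniform prior).
    """

    ngram_table: dict[int, int]
    embeddings: np.ndarray        # (vocab, dim)
    output_weights: np.ndarray    # (classes, dim)
    class_names: tuple[str, ...]
    config: TextConfig = field(default_factory=TextConfig)

    @property
    def dim(self) -> int:
        return int(self.embeddings.shape[1])


def _row_indices(model_table: dict[int, int], name: str, cfg: TextConfig) -> np.ndarray:
    ids = [_fnv1a64(g) % cfg.buckets for g in extract_char_ngrams(name, cfg.n_min, cfg.n_max)]
    rows = [model_table[i] for i in ids if i in model_table]
    return np.asarray(rows, dtype=np.intp)


def train_text_model(
    names: list[str],
    labels: list[str],
    config: TextConfig | None = None,
    class_names: tuple[str, ...] | None = None,
) -> TextModel:
    """Train the supervised embedding classifier by SGD on softmax
    cross-entropy; the document vector is the mean of its n-gram rows.

    Deterministic given ``config.seed``. Raises on a single-class corpus
    ("degenerate task").
    """
    cfg = config or TextConfig()
    if len(names) != len(labels) or not names:
        raise ValueError("names and labels must be equal-length and non-empty")
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("degenerate task: need >= 2 distinct labels")
    if class_names is None:
        class_names = tuple(present)
    else:
        missing = set(labels) - set(class_names)
        if missing:
            raise ValueError(f"labels outside the class set: {sorted(missing)}")
    class_idx = {c: i for i, c in enumerate(class_names)}
    n_classes = len(class_names)

    # build the vocabulary (hash buckets actually seen) and per-doc rows
    table: dict[int, int] = {}
    docs: list[np.ndarray] = []
    for name in names:
        ids = [_fnv1a64(g) % cfg.buckets
               for g in extract_char_ngrams(name, cfg.n_min, cfg.n_max)]
        rows = []
        for i in ids:
            if i not in table:
                table[i] = len(table)
            rows.append(table[i])
        docs.append(np.asarray(rows, dtype=np.intp))
    targets = np.asarray([class_idx[l] for l in labels], dtype=np.intp)

    rng = np.random.default_rng(cfg.seed)
    emb = rng.uniform(-1.0 / cfg.dim, 1.0 / cfg.dim,
                      size=(max(len(table), 1), cfg.dim)).astype(np.float64)
    W = np.zeros((n_classes, cfg.dim))

    total = cfg.epochs * len(docs)
    t = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(docs))
        for di in order:
            rows = docs[di]
            lr = cfg.lr * max(1.0 - t / total, 1e-6)
            t += 1
            if len(rows) == 0:
                continue
            h = emb[rows].mean(axis=0)
            scores = W @ h
            scores -= scores.max()
            p = np.exp(scores)
            p /= p.sum()
            p[targets[di]] -= 1.0  # now the softmax gradient
            grad_h = W.T @ p
            W -= lr * np.outer(p, h)
            emb[rows] -= (lr / len(rows)) * grad_h
    return TextModel(ngram_table=table, embeddings=emb, output_weights=W,
                     class_names=tuple(class_names), config=cfg)


def embed_name(model: TextModel, name: str) -> np.ndarray:
    """Document vector: mean of the name's in-vocabulary n-gram embedding
    rows; the zero vector when nothing is in-vocabulary."""
    rows = _row_indices(model.ngram_table, name, model.config)
    if len(rows) == 0:
        return np.zeros(model.dim)
    return model.embeddings[rows].mean(axis=0)


def predict_text_proba(model: TextModel, name: str) -> np.ndarray:
    """Class posterior (softmax over the linear scores), ordered by
    ``model.class_names``; sums to 1 within 1e-9."""
    scores = model.output_weights @ embed_name(model, name)
    scores -= scores.max()
    p = np.exp(scores)
    return p / p.sum()


def save_text_model(model: TextModel, path: str | Path) -> None:
    """Single binary container with a JSON header."""
    header = json.dumps({
        "format_version": 1,
        "class_names": list(model.class_names),
        "config": vars(model.config),
    })
    ids = np.fromiter(model.ngram_table.keys(), dtype=np.uint64, count=len(model.ngram_table))
    rows = np.fromiter(model.ngram_table.values(), dtype=np.int64, count=len(model.ngram_table))
    np.savez_compressed(str(path), header=np.frombuffer(header.encode(), dtype=np.uint8),
                        ids=ids, rows=rows, embeddings=model.embeddings,
                        output_weights=model.output_weights)


def load_text_model(path: str | Path) -> TextModel:
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        table = dict(zip(z["ids"].astype(int).tolist(), z["rows"].astype(int).tolist()))
        return TextModel(
            ngram_table=table,
            embeddings=z["embeddings"],
            output_weights=z["output_weights"],
            class_names=tuple(header["class_names"]),
            config=TextConfig(**header["config"]),
        )
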