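"""Pixel-wise and object-wise evaluation, and the leave-one-out driver.

The evaluation mirrors the study design: per class, precision
``PRE = TP / (TP + FP)`` and recall ``REC = TP / (TP + FN)`` over evaluable
pixels (ignore-labelled pixels excluded), combined into

    F_beta = (1 + beta^2) * PRE * REC / (beta^2 * PRE + REC)

at beta = 0.5 (precision-weighted) and beta = 1 (Dice).  Object-wise
metrics use the plurality-vote rule: a ground-truth object counts as
correctly classified when its most frequent predicted pixel label equals
its true class.  Object-wise precision for class c divides the correctly
recalled class-c objects by all ground-truth objects whose plurality label
is c (predictions are not segmented into objects).

``run_loo`` drives the full pipeline: for each fold, the spectral
clustering model and the forest are fit on the training images only, the
held-out image is clustered, featurized and classified, and per-class
metrics are collected.  Reported aggregates are per-fold means +/- s.d.
(not pixel-pooled), with a cell-class average excluding the external
region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hsidata import (
    CELL_CLASS_CODES,
    CLASS_CODES,
    CLASS_NAMES,
    IGNORE,
    HyperStack,
    LabelMap,
    flat_field_correct,
)
from .morphfeat import FeatureConfig, extract_features
from .rforest import ForestConfig, train_forest
from .rforest import predict as forest_predict
from .speccluster import fit_kmeans, make_cluster_image, pool_training_spectra
from .synthscene import SceneTruth


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class ClassMetrics:
    pre: float
    rec: float
    f05: float
    f1: float


def f_beta(pre: float, rec: float, beta: float) -> float:
    """F_beta = (1 + b^2) PRE REC / (b^2 PRE + REC); 0 when PRE = REC = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 <= pre <= 1 and 0 <= rec <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if pre == 0 and rec == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * pre * rec / (b2 * pre + rec)


def _metrics_from_counts(tp: int, fp: int, fn: int) -> ClassMetrics:
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    return ClassMetrics(pre, rec, f_beta(pre, rec, 0.5), f_beta(pre, rec, 1.0))


def pixel_metrics(
    pred: LabelMap, truth: LabelMap
) -> tuple[dict[int, ClassMetrics], dict[int, ConfusionCounts]]:
    """Per-class precision/recall/F over evaluable (non-ignore) pixels."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    keep = t != IGNORE
    if not keep.any():
        raise ValueError("no evaluable pixels (all ignore-labelled)")
    t = t[keep].astype(np.int64)
    p = p[keep].astype(np.int64)
    n = t.size
    metrics: dict[int, ClassMetrics] = {}
    counts: dict[int, ConfusionCounts] = {}
    for c in CLASS_CODES:
        tp = int(np.count_nonzero((t == c) & (p == c)))
        fp = int(np.count_nonzero((t != c) & (p == c)))
        fn = int(np.count_nonzero((t == c) & (p != c)))
        tn = n - tp - fp - fn
        counts[c] = ConfusionCounts(tp, fp, fn, tn)
        metrics[c] = _metrics_from_counts(tp, fp, fn)
    return metrics, counts


def object_classify(pred: LabelMap, truth: SceneTruth) -> list[tuple[int, int]]:
    """Plurality label per ground-truth object: (true class, modal predicted
    label) pairs; ties resolve to the lowest class code."""
    out = []
    for obj in truth.objects:
        if obj.pixels.shape[0] == 0:
            raise ValueError(f"object {obj.object_id} has no pixels")
        vals = pred.labels[obj.pixels[:, 0], obj.pixels[:, 1]]
        counts = np.bincount(vals, minlength=max(CLASS_CODES) + 1)
        out.append((obj.class_code, int(np.argmax(counts))))
    return out


def object_metrics(
    pairs: list[tuple[int, int]],
    classes: tuple[int, ...] = CELL_CLASS_CODES,
) -> dict[int, ClassMetrics]:
    """Per-class object-wise metrics from (true class, plurality label) pairs.

    A class absent from both the truth and the plurality labels is omitted
    from the result.  Recall divides by true-c objects; precision divides
    by ground-truth objects whose plurality label is c.
    """
    if len(pairs) == 0:
        raise ValueError("no objects to evaluate")
    out: dict[int, ClassMetrics] = {}
    for c in classes:
        n_true = sum(1 for t, _ in pairs if t == c)
        n_plural = sum(1 for _, p in pairs if p == c)
        if n_true == 0 and n_plural == 0:
            continue
        correct = sum(1 for t, p in pairs if t == c and p == c)
        pre = correct / n_plural if n_plural > 0 else 0.0
        rec = correct / n_true if n_true > 0 else 0.0
        out[c] = ClassMetrics(pre, rec, f_beta(pre, rec, 0.5), f_beta(pre, rec, 1.0))
    return out


# ---------------------------------------------------------------------------
# Leave-one-out driver


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration for the LOO evaluation."""

    n_clusters: int = 32
    kmeans_iter: int = 30
    kmeans_subsample: int = 1_000_000
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    seed: int = 0


@dataclass
class FoldResult:
    fold: int
    pixel: dict[int, ClassMetrics]
    pixel_counts: dict[int, ConfusionCounts]
    object: dict[int, ClassMetrics]
    n_objects: dict[int, int]


@dataclass
class LOOReport:
    folds: list[FoldResult]
    class_codes: tuple[int, ...] = CLASS_CODES

    # -- aggregation ---------------------------------------------------

    def _collect(self, kind: str, code: int, metric: str) -> np.ndarray:
        vals = []
        for f in self.folds:
            table = f.pixel if kind == "pixel" else f.object
            if code in table:
                vals.append(getattr(table[code], metric))
            else:
                vals.append(np.nan)
        return np.asarray(vals, dtype=float)

    def class_mean(self, kind: str, code: int, metric: str) -> tuple[float, float]:
        """Mean +/- s.d. over folds of one per-class metric."""
        vals = self._collect(kind, code, metric)
        return float(np.nanmean(vals)), float(np.nanstd(vals))

    def cell_average(self, kind: str, metric: str) -> tuple[float, float]:
        """Per-fold average over the three cell classes (external excluded),
        then mean +/- s.d. over folds."""
        per_fold = []
        for f in self.folds:
            table = f.pixel if kind == "pixel" else f.object
            vals = [getattr(table[c], metric) for c in CELL_CLASS_CODES if c in table]
            per_fold.append(np.nanmean(vals) if vals else np.nan)
        arr = np.asarray(per_fold, dtype=float)
        return float(np.nanmean(arr)), float(np.nanstd(arr))

    def summary_frame(self) -> pd.DataFrame:
        """A table of per-class and cell-average metrics (mean over folds)."""
        rows = []
        for kind in ("pixel", "object"):
            codes = CLASS_CODES if kind == "pixel" else CELL_CLASS_CODES
            for c in codes:
                row = {"scheme": kind, "class": CLASS_NAMES[c]}
                for metric in ("pre", "rec", "f05", "f1"):
                    m, s = self.class_mean(kind, c, metric)
                    row[metric] = m
                    row[metric + "_sd"] = s
                rows.append(row)
            row = {"scheme": kind, "class": "average (excl. external)"}
            for metric in ("pre", "rec", "f05", "f1"):
                m, s = self.cell_average(kind, metric)
                row[metric] = m
                row[metric + "_sd"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        def cm(m: ClassMetrics) -> dict:
            return {"pre": m.pre, "rec": m.rec, "f05": m.f05, "f1": m.f1}

        obj = {
            "class_codes": list(self.class_codes),
            "folds": [
                {
                    "fold": f.fold,
                    "pixel": {str(c): cm(m) for c, m in f.pixel.items()},
                    "pixel_counts": {
                        str(c): [v.tp, v.fp, v.fn, v.tn]
                        for c, v in f.pixel_counts.items()
                    },
                    "object": {str(c): cm(m) for c, m in f.object.items()},
                    "n_objects": {str(c): n for c, n in f.n_objects.items()},
                }
                for f in self.folds
            ],
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LOOReport":
        obj = json.loads(text)

        def cm(d: dict) -> ClassMetrics:
            return ClassMetrics(d["pre"], d["rec"], d["f05"], d["f1"])

        folds = [
            FoldResult(
                fold=f["fold"],
                pixel={int(c): cm(m) for c, m in f["pixel"].items()},
                pixel_counts={
                    int(c): ConfusionCounts(*v) for c, v in f["pixel_counts"].items()
                },
                object={int(c): cm(m) for c, m in f["object"].items()},
                n_objects={int(c): n for c, n in f["n_objects"].items()},
            )
            for f in obj["folds"]
        ]
        return cls(folds=folds, class_codes=tuple(obj["class_codes"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "LOOReport":
        return cls.from_json(Path(path).read_text())


Scene = tuple[HyperStack, HyperStack, HyperStack, SceneTruth]


def _masked_labels(truth: SceneTruth, corrected: HyperStack) -> LabelMap:
    """Ground-truth labels with invalid-FFC pixels switched to ignore."""
    if corrected.invalid is None or not corrected.invalid.any():
        return truth.labels
    lab = truth.labels.labels.copy()
    lab[corrected.invalid] = IGNORE
    return LabelMap(lab)


def run_loo(scenes: list[Scene], config: PipelineConfig | None = None) -> LOOReport:
    """Leave-one-out cross-validation of the full pipeline.

    Per fold: flat-field-correct every image; fit the k-means model on the
    training images' pooled spectra; build cluster images for all images
    with that model; extract features; train the forest on the training
    images; classify the held-out image; compute pixel- and object-wise
    metrics.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = PipelineConfig()
    n = len(scenes)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 images")
    corrected = [flat_field_correct(O, D, F) for O, D, F, _ in scenes]
    truths = [t for _, _, _, t in scenes]
    labels = [_masked_labels(t, c) for t, c in zip(truths, corrected)]
    folds = []
    for test_idx in range(n):
        train_idx = [i for i in range(n) if i != test_idx]
        assert test_idx not in train_idx  # fold contamination is structural
        ss = np.random.SeedSequence([config.seed, test_idx])
        km_seed, rf_seed = (int(s) for s in ss.generate_state(2) >> 1)
        pool = pool_training_spectra(
            [corrected[i] for i in train_idx],
            subsample_cap=config.kmeans_subsample,
            seed=km_seed,
        )
        model = fit_kmeans(
            pool, k=config.n_clusters, n_iter=config.kmeans_iter, seed=km_seed
        )
        feats = {
            i: extract_features(make_cluster_image(model, corrected[i]), config.feature)
            for i in range(n)
        }
        forest = train_forest(
            [feats[i] for i in train_idx],
            [labels[i] for i in train_idx],
            config=ForestConfig(
                n_trees=config.forest.n_trees,
                max_depth=config.forest.max_depth,
                n_candidates=config.forest.n_candidates,
                per_tree_sample=config.forest.per_tree_sample,
                min_samples_leaf=config.forest.min_samples_leaf,
                seed=rf_seed,
                rule_types=config.forest.rule_types,
            ),
        )
        pred = forest_predict(forest, feats[test_idx])
        pix, cnt = pixel_metrics(pred, labels[test_idx])
        pairs = object_classify(pred, truths[test_idx])
        obj = object_metrics(pairs)
        n_objects = {
            c: sum(1 for t, _ in pairs if t == c) for c in CELL_CLASS_CODES
        }
        folds.append(
            FoldResult(
                fold=test_idx,
                pixel=pix,
                pixel_counts=cnt,
                object=obj,
                n_objects=n_objects,
            )
        )
    return LOOReport(folds=folds)
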