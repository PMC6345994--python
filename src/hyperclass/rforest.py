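"""Random Forest with single-feature and feature-difference split rules.

Each internal node compares either one feature value, or the difference of
two feature values, against a threshold; the latter rule family realizes
oblique decision boundaries along ``f_i - f_j = t`` that axis-aligned trees
can only approximate.  Trees are grown greedily: at every node a fixed
number of candidate rules (random type, random feature indices, threshold
drawn uniformly from the node-local range of the rule's expression) is
scored by Shannon entropy reduction, and the best candidate is kept.
Growth stops at the depth limit, on pure or degenerate nodes, or when no
candidate reduces the entropy; leaves store class generation probabilities
(the class frequencies of the training samples that reached them).

Prediction averages the leaf probability vectors over all trees and takes
the argmax (ties resolved toward the lowest class code).

Samples with expression value <= threshold go to the left child.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .hsidata import CLASS_CODES, IGNORE, LabelMap
from .morphfeat import FeatureStack

SINGLE = "single"
DIFFERENCE = "difference"

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class SplitRule:
    rule_type: str  # "single" or "difference"
    i: int
    j: int | None = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.rule_type not in (SINGLE, DIFFERENCE):
            raise ValueError(f"unknown rule type {self.rule_type!r}")
        if self.rule_type == DIFFERENCE and (self.j is None or self.j == self.i):
            raise ValueError("difference rules need a distinct second feature")

    def expression(self, X: np.ndarray) -> np.ndarray:
        if self.rule_type == SINGLE:
            return X[:, self.i]
        return X[:, self.i] - X[:, self.j]


@dataclass
class TreeNode:
    """Either an internal node (rule, left, right) or a leaf (class_probs)."""

    rule: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    class_probs: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass(frozen=True)
class ForestConfig:
    """Hyper-parameters; defaults follow the published configuration
    (100 trees, depth <= 50, 400 candidate rules per node)."""

    n_trees: int = 100
    max_depth: int = 50
    n_candidates: int = 400
    per_tree_sample: int = 100_000
    min_samples_leaf: int = 1
    seed: int = 0
    rule_types: tuple[str, ...] = (SINGLE, DIFFERENCE)

    def __post_init__(self) -> None:
        for name in ("n_trees", "n_candidates", "per_tree_sample", "min_samples_leaf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if not self.rule_types or set(self.rule_types) - {SINGLE, DIFFERENCE}:
            raise ValueError("rule_types must be a non-empty subset of "
                             "{'single', 'difference'}")


@dataclass
class ForestModel:
    trees: list[TreeNode]
    config: ForestConfig
    classes: tuple[int, ...]
    feature_names: tuple[str, ...] | None = None

    def to_json(self) -> str:
        def node_obj(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"class_probs": [float(p) for p in node.class_probs]}
            r = node.rule
            return {
                "rule_type": r.rule_type,
                "i": r.i,
                "j": r.j,
                "threshold": float(r.threshold),
                "left": node_obj(node.left),
                "right": node_obj(node.right),
            }

        obj = {
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "n_candidates": self.config.n_candidates,
                "per_tree_sample": self.config.per_tree_sample,
                "min_samples_leaf": self.config.min_samples_leaf,
                "seed": self.config.seed,
                "rule_types": list(self.config.rule_types),
            },
            "classes": list(self.classes),
            "feature_names": None
            if self.feature_names is None
            else list(self.feature_names),
            "trees": [node_obj(t) for t in self.trees],
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        obj = json.loads(text)

        def parse(d: dict) -> TreeNode:
            if "class_probs" in d:
                return TreeNode(class_probs=np.asarray(d["class_probs"]))
            rule = SplitRule(d["rule_type"], d["i"], d["j"], d["threshold"])
            return TreeNode(rule=rule, left=parse(d["left"]), right=parse(d["right"]))

        cfg = obj["config"]
        config = ForestConfig(
            n_trees=cfg["n_trees"],
            max_depth=cfg["max_depth"],
            n_candidates=cfg["n_candidates"],
            per_tree_sample=cfg["per_tree_sample"],
            min_samples_leaf=cfg["min_samples_leaf"],
            seed=cfg["seed"],
            rule_types=tuple(cfg["rule_types"]),
        )
        names = obj.get("feature_names")
        return cls(
            trees=[parse(t) for t in obj["trees"]],
            config=config,
            classes=tuple(obj["classes"]),
            feature_names=None if names is None else tuple(names),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Entropy and split search


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of the class frequencies of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _counts_entropy(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Entropy in bits from class-count columns; counts (C, m), n (m,)."""
    p = counts / n
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=counts > 0)
    return -(p * logp).sum(axis=0)


def _propose_arrays(
    X: np.ndarray,
    n_candidates: int,
    rng: np.random.Generator,
    rule_types: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Vectorized candidate generation on the node's samples.

    Returns (types, ii, jj, thresholds, E) with E the (n, m) expression
    matrix, or None for a degenerate node (every feature constant, hence
    every expression constant).
    """
    n, F = X.shape
    if np.all(X.min(axis=0) == X.max(axis=0)):
        return None
    allow_diff = DIFFERENCE in rule_types and F >= 2
    allow_single = SINGLE in rule_types
    if allow_single and allow_diff:
        types = rng.integers(0, 2, size=n_candidates)  # 0 single, 1 difference
    elif allow_single:
        types = np.zeros(n_candidates, dtype=np.int64)
    else:
        if F < 2:
            return None
        types = np.ones(n_candidates, dtype=np.int64)
    ii = rng.integers(0, F, size=n_candidates)
    jj = rng.integers(0, F - 1, size=n_candidates) if F > 1 else np.zeros(n_candidates, dtype=np.int64)
    jj[jj >= ii] += 1  # distinct pair, uniform over j != i
    E = X[:, ii].copy()
    d = types == 1
    if d.any():
        E[:, d] -= X[:, jj[d]]
    lo = E.min(axis=0)
    hi = E.max(axis=0)
    thr = rng.uniform(lo, hi)
    return types, ii, jj, thr, E


def propose_candidates(
    samples: np.ndarray,
    labels: np.ndarray,
    n_candidates: int,
    rng: np.random.Generator,
    rule_types: tuple[str, ...] = (SINGLE, DIFFERENCE),
) -> list[SplitRule]:
    """Randomly chosen rules (combination of type, features and threshold).

    Rule type is chosen uniformly among the allowed types (no difference
    rules exist for a single feature); feature indices are uniform (a
    distinct pair for difference rules); the threshold is uniform between
    the min and max of the rule's expression over the node's samples.
    Degenerate nodes (all expressions constant) yield an empty list.
    """
    X = np.asarray(samples, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("a node needs at least 2 samples to propose splits")
    out = _propose_arrays(X, n_candidates, rng, rule_types)
    if out is None:
        return []
    types, ii, jj, thr, _ = out
    rules = []
    for t, i, j, th in zip(types, ii, jj, thr):
        if t == 0:
            rules.append(SplitRule(SINGLE, int(i), None, float(th)))
        else:
            rules.append(SplitRule(DIFFERENCE, int(i), int(j), float(th)))
    return rules


def _best_from_matrix(
    E: np.ndarray,
    thr: np.ndarray,
    y_onehot: np.ndarray,
    min_samples_leaf: int,
) -> tuple[int, float, np.ndarray] | None:
    """Best candidate column by entropy gain; None if no valid positive gain.

    Returns (candidate index, gain in bits, left mask over samples).
    """
    n = E.shape[0]
    mask = E <= thr  # (n, m) left assignment
    left = y_onehot.T @ mask.astype(np.float32)  # (C, m) exact counts
    total = y_onehot.sum(axis=0, dtype=np.float64)[:, None]  # (C, 1)
    left = left.astype(np.float64)
    right = total - left
    n_left = left.sum(axis=0)
    n_right = right.sum(axis=0)
    valid = (n_left >= min_samples_leaf) & (n_right >= min_samples_leaf)
    if not valid.any():
        return None
    h_parent = _counts_entropy(total, np.array([float(n)]))[0]
    h_left = _counts_entropy(left, np.maximum(n_left, 1.0))
    h_right = _counts_entropy(right, np.maximum(n_right, 1.0))
    gain = h_parent - (n_left * h_left + n_right * h_right) / n
    gain[~valid] = -np.inf
    best = int(np.argmax(gain))
    if gain[best] <= _GAIN_EPS:
        return None
    return best, float(gain[best]), mask[:, best]


def best_split(
    samples: np.ndarray,
    labels: np.ndarray,
    candidates: list[SplitRule],
    min_samples_leaf: int = 1,
) -> tuple[SplitRule, float] | None:
    """The candidate maximizing entropy reduction (parent entropy minus
    size-weighted child entropies); None when no candidate has positive gain
    or every candidate leaves a child empty.  Equal gains go to the first
    candidate proposed."""
    if not candidates:
        return None
    X = np.asarray(samples, dtype=np.float64)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    y1h = np.zeros((y.size, classes.size), dtype=np.float32)
    y1h[np.arange(y.size), y_idx] = 1.0
    E = np.stack([r.expression(X) for r in candidates], axis=1)
    thr = np.array([r.threshold for r in candidates])
    found = _best_from_matrix(E, thr, y1h, min_samples_leaf)
    if found is None:
        return None
    best, gain, _ = found
    return candidates[best], gain


# ---------------------------------------------------------------------------
# Training
#
# The node split search is the hot loop of training: every node scores a
# few hundred candidate rules over all of its samples.  The scans below
# read the transposed (features, samples) matrix directly instead of
# materializing an (n_samples, n_candidates) expression matrix.


@njit(cache=True)
def _expr_ranges(XT, types, ii, jj):  # pragma: no cover - exercised via _grow
    """Min/max of each candidate rule's expression over the node samples."""
    m = types.size
    n = XT.shape[1]
    lo = np.empty(m, dtype=np.float32)
    hi = np.empty(m, dtype=np.float32)
    for c in range(m):
        i = ii[c]
        j = jj[c]
        if types[c] == 0:
            v0 = XT[i, 0]
        else:
            v0 = XT[i, 0] - XT[j, 0]
        a = v0
        b = v0
        for s in range(1, n):
            if types[c] == 0:
                v = XT[i, s]
            else:
                v = XT[i, s] - XT[j, s]
            if v < a:
                a = v
            elif v > b:
                b = v
        lo[c] = a
        hi[c] = b
    return lo, hi


@njit(cache=True)
def _left_counts(XT, y_idx, types, ii, jj, thr, n_classes):  # pragma: no cover
    """Class counts of the left child (expression <= threshold) per rule."""
    m = types.size
    n = XT.shape[1]
    counts = np.zeros((n_classes, m), dtype=np.int64)
    for c in range(m):
        i = ii[c]
        j = jj[c]
        t = thr[c]
        if types[c] == 0:
            for s in range(n):
                if XT[i, s] <= t:
                    counts[y_idx[s], c] += 1
        else:
            for s in range(n):
                if XT[i, s] - XT[j, s] <= t:
                    counts[y_idx[s], c] += 1
    return counts


def _best_split_fast(
    X: np.ndarray,
    y_idx: np.ndarray,
    n_classes: int,
    config: "ForestConfig",
    rng: np.random.Generator,
) -> tuple[SplitRule, np.ndarray] | None:
    """Propose candidates and pick the best by entropy gain (training path).

    Semantics match ``propose_candidates`` + ``best_split``: uniform rule
    type, uniform feature indices (distinct pair for differences),
    thresholds uniform over the node-local expression range, gain measured
    in bits, first-proposed wins ties, None when nothing attains positive
    gain with both children >= min_samples_leaf.
    """
    n, F = X.shape
    XT = np.ascontiguousarray(X.T)
    if np.all(XT.min(axis=1) == XT.max(axis=1)):
        return None  # degenerate node: every expression is constant
    allow_diff = DIFFERENCE in config.rule_types and F >= 2
    allow_single = SINGLE in config.rule_types
    m = config.n_candidates
    if allow_single and allow_diff:
        types = rng.integers(0, 2, size=m)
    elif allow_single:
        types = np.zeros(m, dtype=np.int64)
    elif F >= 2:
        types = np.ones(m, dtype=np.int64)
    else:
        return None
    ii = rng.integers(0, F, size=m)
    jj = rng.integers(0, F - 1, size=m) if F > 1 else np.zeros(m, dtype=np.int64)
    jj[jj >= ii] += 1
    lo, hi = _expr_ranges(XT, types, ii, jj)
    thr = rng.uniform(lo.astype(np.float64), hi.astype(np.float64))
    left = _left_counts(XT, y_idx, types, ii, jj, thr, n_classes).astype(np.float64)
    total = np.bincount(y_idx, minlength=n_classes).astype(np.float64)[:, None]
    right = total - left
    n_left = left.sum(axis=0)
    n_right = right.sum(axis=0)
    valid = (n_left >= config.min_samples_leaf) & (n_right >= config.min_samples_leaf)
    if not valid.any():
        return None
    h_parent = _counts_entropy(total, np.array([float(n)]))[0]
    gain = h_parent - (
        n_left * _counts_entropy(left, np.maximum(n_left, 1.0))
        + n_right * _counts_entropy(right, np.maximum(n_right, 1.0))
    ) / n
    gain[~valid] = -np.inf
    best = int(np.argmax(gain))
    if gain[best] <= _GAIN_EPS:
        return None
    if types[best] == 0:
        rule = SplitRule(SINGLE, int(ii[best]), None, float(thr[best]))
        left_mask = X[:, rule.i] <= rule.threshold
    else:
        rule = SplitRule(DIFFERENCE, int(ii[best]), int(jj[best]), float(thr[best]))
        left_mask = (X[:, rule.i] - X[:, rule.j]) <= rule.threshold
    return rule, left_mask


def _grow(
    X: np.ndarray,
    y_idx: np.ndarray,
    n_classes: int,
    config: ForestConfig,
    rng: np.random.Generator,
    depth: int,
) -> TreeNode:
    counts = np.bincount(y_idx, minlength=n_classes)
    n = y_idx.size

    def leaf() -> TreeNode:
        return TreeNode(class_probs=counts / n)

    if (
        depth >= config.max_depth
        or n < 2 * config.min_samples_leaf
        or np.count_nonzero(counts) <= 1
    ):
        return leaf()
    found = _best_split_fast(X, y_idx, n_classes, config, rng)
    if found is None:
        return leaf()
    rule, left_mask = found
    return TreeNode(
        rule=rule,
        left=_grow(X[left_mask], y_idx[left_mask], n_classes, config, rng, depth + 1),
        right=_grow(X[~left_mask], y_idx[~left_mask], n_classes, config, rng, depth + 1),
    )


def train_tree(
    samples: np.ndarray,
    labels: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
    classes: tuple[int, ...] | None = None,
) -> TreeNode:
    """Grow one tree on (samples, labels); leaf probabilities are the class
    frequencies of the training data reaching each leaf."""
    X = np.ascontiguousarray(np.asarray(samples, dtype=np.float32))
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("cannot train a tree on an empty set")
    if classes is None:
        classes = tuple(int(c) for c in np.unique(y))
    lut = {c: k for k, c in enumerate(classes)}
    y_idx = np.asarray([lut[int(v)] for v in y], dtype=np.int64)
    return _grow(X, y_idx, len(classes), config, rng, 0)


def tree_depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(tree_depth(node.left), tree_depth(node.right))


def _stratified_bootstrap(
    y_idx: np.ndarray, n_classes: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap sample (with replacement) of at most ``cap`` indices,
    stratified so each class keeps its pooled share (>= 1 per class)."""
    n = y_idx.size
    size = min(cap, n)
    picks = []
    for k in range(n_classes):
        members = np.nonzero(y_idx == k)[0]
        if members.size == 0:
            continue
        take = max(1, int(round(size * members.size / n)))
        picks.append(rng.choice(members, size=take, replace=True))
    return np.concatenate(picks)


def train_forest(
    features: list[FeatureStack] | list[np.ndarray],
    labels: list[LabelMap] | list[np.ndarray],
    config: ForestConfig | None = None,
    classes: tuple[int, ...] = CLASS_CODES,
    feature_names: tuple[str, ...] | None = None,
) -> ForestModel:
    """Train a forest on pooled per-pixel samples from one or more images.

    Ignore-labelled (255) pixels are excluded from the pool.  Each tree
    receives its own seeded, stratified bootstrap sample (with replacement,
    capped at ``per_tree_sample``).  Raises if any required class is absent
    from all training data.
    """
    if config is None:
        config = ForestConfig()
    if len(features) == 0 or len(features) != len(labels):
        raise ValueError("need matching, non-empty feature and label lists")
    X_parts, y_parts = [], []
    for fs, lm in zip(features, labels):
        Xi = fs.as_matrix() if isinstance(fs, FeatureStack) else np.asarray(fs)
        yi = (lm.labels if isinstance(lm, LabelMap) else np.asarray(lm)).ravel()
        keep = yi != IGNORE
        X_parts.append(np.asarray(Xi, dtype=np.float32)[keep])
        y_parts.append(yi[keep])
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts)
    present = set(int(v) for v in np.unique(y))
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes absent from all training data: {missing}")
    lut = np.full(max(classes) + 1, -1, dtype=np.int64)
    for k, c in enumerate(classes):
        lut[c] = k
    y_idx = lut[y]
    if feature_names is None and isinstance(features[0], FeatureStack):
        feature_names = features[0].names
    ss = np.random.SeedSequence(config.seed)
    trees = []
    for child in ss.spawn(config.n_trees):
        rng = np.random.default_rng(child)
        take = _stratified_bootstrap(y_idx, len(classes), config.per_tree_sample, rng)
        trees.append(
            _grow(X[take], y_idx[take], len(classes), config, rng, 0)
        )
    return ForestModel(
        trees=trees, config=config, classes=tuple(classes), feature_names=feature_names
    )


# ---------------------------------------------------------------------------
# Prediction


def _tree_proba(node: TreeNode, X: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.empty((X.shape[0], n_classes), dtype=np.float64)
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if idx.size == 0:
            continue
        if nd.is_leaf:
            out[idx] = nd.class_probs
            continue
        e = nd.rule.expression(X[idx])
        m = e <= nd.rule.threshold
        stack.append((nd.left, idx[m]))
        stack.append((nd.right, idx[~m]))
    return out


def _as_matrix(features: FeatureStack | np.ndarray) -> tuple[np.ndarray, tuple[int, int] | None]:
    if isinstance(features, FeatureStack):
        f, H, W = features.planes.shape
        return features.as_matrix(), (H, W)
    X = np.asarray(features)
    return X, None


def predict_proba(
    model: ForestModel, features: FeatureStack | np.ndarray
) -> np.ndarray:
    """Mean of per-tree leaf generation probabilities; rows sum to 1."""
    X, _ = _as_matrix(features)
    n_feat_expected = _model_n_features(model)
    if n_feat_expected is not None and X.shape[1] != n_feat_expected:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({n_feat_expected})"
        )
    X = np.asarray(X, dtype=np.float32)
    acc = np.zeros((X.shape[0], len(model.classes)), dtype=np.float64)
    for tree in model.trees:
        acc += _tree_proba(tree, X, len(model.classes))
    acc /= len(model.trees)
    return acc


def _model_n_features(model: ForestModel) -> int | None:
    """Expected feature count, known only when feature names were recorded."""
    if model.feature_names is not None:
        return len(model.feature_names)
    return None


def predict(
    model: ForestModel, features: FeatureStack | np.ndarray
) -> LabelMap | np.ndarray:
    """Argmax class of the averaged probabilities (ties -> lowest class code).

    Returns a LabelMap when given a FeatureStack, else a flat code array.
    """
    X, shape = _as_matrix(features)
    proba = predict_proba(model, X)
    codes = np.asarray(model.classes, dtype=np.uint8)[np.argmax(proba, axis=1)]
    if shape is not None:
        return LabelMap(codes.reshape(shape))
    return codes
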