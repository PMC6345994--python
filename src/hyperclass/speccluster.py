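"""Spectrum-wise k-means information reduction and cluster images.

Raw 25-band pixel spectra carry too much redundancy for a pixel classifier,
so they are first quantized into k spectral categories by k-means (k-means++
seeding, a fixed number of Lloyd updates, Euclidean distance over the 25
corrected band values).  The resulting *cluster image* replaces each pixel
by a value encoding its cluster's rank by mean centroid intensity (rank 0 =
darkest cluster), linearly scaled to 8 bits, so that the single-channel
image remains ordinal in brightness while carrying the spectral category.

The clusterer is implemented here rather than delegated, because its exact
semantics (fixed 30 updates with no early exit, farthest-point re-seeding
of empty clusters, lowest-index tie-breaking) are part of the pipeline
contract and are asserted by the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hsidata import HyperStack

_CHUNK = 1 << 18  # pixels per distance block; bounds peak memory


@dataclass
class ClusterModel:
    """k centroids in spectral space plus the fit bookkeeping."""

    centroids: np.ndarray  # (k, n_bands)
    k: int
    n_iter: int
    seed: int
    wavelengths_nm: np.ndarray | None = None
    inertia_history: list[float] = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return self.centroids.shape[1]

    def to_json(self) -> str:
        obj = {
            "k": self.k,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "wavelengths_nm": None
            if self.wavelengths_nm is None
            else [float(w) for w in self.wavelengths_nm],
            "centroids": [[float(v) for v in row] for row in self.centroids],
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        obj = json.loads(text)
        wl = obj.get("wavelengths_nm")
        return cls(
            centroids=np.asarray(obj["centroids"], dtype=np.float64),
            k=int(obj["k"]),
            n_iter=int(obj["n_iter"]),
            seed=int(obj["seed"]),
            wavelengths_nm=None if wl is None else np.asarray(wl, dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class ClusterImage:
    """Cluster ids plus the intensity-ranked 8-bit display channel."""

    ids: np.ndarray  # (H, W) int32 in [0, k)
    display: np.ndarray  # (H, W) uint8, function of id only
    k: int


def _sq_dists(
    X: np.ndarray, C: np.ndarray, xn: np.ndarray | None = None
) -> np.ndarray:
    """Squared Euclidean distances (n, k) via the expanded form; ``xn`` may
    carry precomputed row norms of X."""
    if xn is None:
        xn = np.einsum("ij,ij->i", X, X)
    d2 = X @ C.T
    d2 *= -2.0
    d2 += xn[:, None]
    d2 += np.einsum("ij,ij->i", C, C)[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def _kmeanspp_init(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: iteratively sample points with probability
    proportional to squared distance from the nearest chosen centroid."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]), dtype=X.dtype)
    first = int(rng.integers(0, n))
    centroids[0] = X[first]
    d2 = _sq_dists(X, centroids[:1]).ravel()
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            idx = int(rng.integers(0, n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[i] = X[idx]
        d2 = np.minimum(d2, _sq_dists(X, centroids[i : i + 1]).ravel())
    return centroids


def fit_kmeans(
    pixels: np.ndarray,
    k: int,
    n_iter: int = 30,
    seed: int = 0,
) -> ClusterModel:
    """Fit k-means with k-means++ seeding and exactly ``n_iter`` Lloyd updates.

    No convergence early-exit is used: a converged model is simply updated
    idempotently.  An empty cluster arising during an update is re-seeded
    with the point currently farthest from its assigned centroid, keeping k
    fixed.  Deterministic given ``seed``.  ``inertia_history`` records the
    within-cluster sum of squares at each assignment step (non-increasing).
    """
    X = np.ascontiguousarray(np.asarray(pixels, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("pixels must be a non-empty (N, bands) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("pixel spectra must be finite")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} spectra, got {n}")
    rng = np.random.default_rng(seed)
    # Distances in float32 (fast path); centroid updates accumulate in
    # float64 from the original values.
    X32 = X.astype(np.float32)
    xn32 = np.einsum("ij,ij->i", X32, X32)
    C = _kmeanspp_init(X, k, rng)
    history: list[float] = []
    for _ in range(n_iter):
        d2 = _sq_dists(X32, C.astype(np.float32), xn32)
        labels = np.argmin(d2, axis=1)
        mind2 = d2[np.arange(n), labels].astype(np.float64)
        history.append(float(mind2.sum()))
        counts = np.bincount(labels, minlength=k)
        empties = np.nonzero(counts == 0)[0]
        for e in empties:
            far = int(np.argmax(mind2))
            labels[far] = e
            mind2[far] = -np.inf  # a point re-seeds at most one empty cluster
        sums = np.stack(
            [np.bincount(labels, weights=X[:, b], minlength=k) for b in range(X.shape[1])],
            axis=1,
        )
        C = sums / np.bincount(labels, minlength=k)[:, None]
    return ClusterModel(
        centroids=C, k=k, n_iter=n_iter, seed=seed, inertia_history=history
    )


def predict(model: ClusterModel, pixels: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) cluster index per spectrum; ties go to
    the lowest index (argmin semantics)."""
    X = np.asarray(pixels, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_bands:
        raise ValueError(
            f"expected (N, {model.n_bands}) spectra, got {X.shape}"
        )
    out = np.empty(X.shape[0], dtype=np.int32)
    for start in range(0, X.shape[0], _CHUNK):
        block = X[start : start + _CHUNK]
        out[start : start + _CHUNK] = np.argmin(_sq_dists(block, model.centroids), axis=1)
    return out


def display_values(model: ClusterModel) -> np.ndarray:
    """Per-cluster 8-bit display value: rank of the cluster by centroid mean
    intensity over the bands (rank 0 = darkest), linearly scaled to 0-255."""
    means = model.centroids.mean(axis=1)
    order = np.argsort(means, kind="stable")
    ranks = np.empty(model.k, dtype=np.int64)
    ranks[order] = np.arange(model.k)
    if model.k == 1:
        return np.zeros(1, dtype=np.uint8)
    return np.rint(255.0 * ranks / (model.k - 1)).astype(np.uint8)


def make_cluster_image(model: ClusterModel, corrected: HyperStack) -> ClusterImage:
    """Cluster every pixel of a corrected stack and build the display image."""
    if corrected.n_bands != model.n_bands:
        raise ValueError(
            f"stack has {corrected.n_bands} bands, model expects {model.n_bands}"
        )
    bands, H, W = corrected.shape
    spectra = corrected.data.reshape(bands, H * W).T
    ids = predict(model, spectra).reshape(H, W)
    disp = display_values(model)[ids]
    return ClusterImage(ids=ids.astype(np.int32), display=disp, k=model.k)


def cluster_mean_spectra(
    model: ClusterModel, corrected: HyperStack, cimg: ClusterImage
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster per-band mean and population s.d. over member pixels.

    Returns ``(means, sds, counts)`` each with k rows; empty clusters get
    zero mean/s.d. and count 0.
    """
    bands, H, W = corrected.shape
    X = corrected.data.reshape(bands, H * W).astype(np.float64)
    ids = cimg.ids.ravel()
    k = model.k
    counts = np.bincount(ids, minlength=k)
    means = np.zeros((k, bands))
    sds = np.zeros((k, bands))
    safe = np.maximum(counts, 1)
    for b in range(bands):
        s = np.bincount(ids, weights=X[b], minlength=k)
        s2 = np.bincount(ids, weights=X[b] ** 2, minlength=k)
        mu = s / safe
        var = np.maximum(s2 / safe - mu**2, 0.0)
        means[:, b] = mu
        sds[:, b] = np.sqrt(var)
    means[counts == 0] = 0.0
    sds[counts == 0] = 0.0
    return means, sds, counts


def pool_training_spectra(
    stacks: list[HyperStack],
    subsample_cap: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Pool pixel spectra from corrected stacks for model fitting, with a
    seeded uniform subsample cap to bound memory on large image sets.

    Pixels flagged invalid by flat-field correction are excluded.
    """
    parts = []
    for st in stacks:
        bands, H, W = st.shape
        X = st.data.reshape(bands, H * W).T
        if st.invalid is not None and st.invalid.any():
            X = X[~st.invalid.ravel()]
        parts.append(X)
    pooled = np.concatenate(parts, axis=0)
    if pooled.shape[0] > subsample_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(pooled.shape[0], size=subsample_cap, replace=False)
        pooled = pooled[np.sort(idx)]
    return pooled
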