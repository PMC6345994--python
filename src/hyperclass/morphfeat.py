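"""Multi-scale morphological (texture and edge-based) features.

From the single-channel cluster image four feature families are computed
inside a kernel-sized local window: the Hessian (second derivatives and
their eigenvalues), the Laplacian, the local standard deviation and the
circular standard deviation of gradient orientations.  Each family is
evaluated at three spatial scales (the original image plus area-averaged
half- and quarter-size versions), and all planes are brought back to full
resolution, yielding 24 feature planes per pixel under the defaults.

Derivatives are Gaussian-derivative responses with standard deviation
``kernel / 4`` and a filter radius of ``kernel // 2`` pixels, i.e. the
named 7-px kernel; reflect padding is used at all borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .speccluster import ClusterImage

#: Per-scale plane names of the default 24-feature configuration.
DEFAULT_PLANES = (
    "intensity",
    "hxx",
    "hyy",
    "hxy",
    "eig1",
    "eig2",
    "local_std",
    "circ_std",
)

DEFAULT_SCALES = (1.0, 0.5, 0.25)

#: Circular standard deviation cap: sqrt(-2 ln R) evaluated at R = 1e-6.
CIRC_STD_CAP = float(np.sqrt(-2.0 * np.log(1e-6)))


@dataclass(frozen=True)
class FeatureConfig:
    kernel: int = 7
    scales: tuple[float, ...] = DEFAULT_SCALES
    per_scale_features: tuple[str, ...] = DEFAULT_PLANES

    def __post_init__(self) -> None:
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 3")
        if any(not (0 < s <= 1) for s in self.scales):
            raise ValueError("scales must lie in (0, 1]")
        known = set(DEFAULT_PLANES) | {"laplacian"}
        unknown = [n for n in self.per_scale_features if n not in known]
        if unknown:
            raise ValueError(f"unknown feature plane names: {unknown}")

    @property
    def total_features(self) -> int:
        return len(self.per_scale_features) * len(self.scales)


@dataclass
class FeatureStack:
    """total_features x H x W planes at full resolution, with stable names."""

    planes: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.planes.shape[0] != len(self.names):
            raise ValueError("plane count must match name count")
        if not np.all(np.isfinite(self.planes)):
            raise ValueError("feature planes must be finite")

    @property
    def n_features(self) -> int:
        return self.planes.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(n_pixels, n_features) design matrix, row-major pixel order."""
        f, H, W = self.planes.shape
        return self.planes.reshape(f, H * W).T


def _check_size(img: np.ndarray, kernel: int) -> None:
    if img.shape[0] < kernel or img.shape[1] < kernel:
        raise ValueError(
            f"image {img.shape} is smaller than the {kernel}-px kernel"
        )


def _deriv_kernel(kernel: int, order: int) -> np.ndarray:
    """Gaussian-derivative tap weights of width ``kernel`` (sigma = kernel/4),
    moment-normalized so the operator is exact on polynomials up to the
    derivative order (a bare truncated Gaussian derivative leaks low-order
    polynomial terms at this small a support)."""
    sigma = kernel / 4.0
    r = kernel // 2
    m = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (m / sigma) ** 2)
    if order == 0:
        return g / g.sum()
    if order == 1:
        w = -m * g
        return w / np.dot(m, w)  # sum(m * w) = 1
    if order == 2:
        w = (m**2 - np.dot(m**2, g) / g.sum()) * g  # sum(w) = 0
        return w * (2.0 / np.dot(m**2, w))  # sum(m^2 * w) = 2
    raise ValueError("derivative order must be 0, 1 or 2")


def _gauss(img: np.ndarray, kernel: int, order: tuple[int, int]) -> np.ndarray:
    out = ndimage.correlate1d(img, _deriv_kernel(kernel, order[0]), axis=0, mode="reflect")
    return ndimage.correlate1d(out, _deriv_kernel(kernel, order[1]), axis=1, mode="reflect")


def hessian_planes(img: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Hxx, Hyy, Hxy and the sorted Hessian eigenvalues (lam1 >= lam2).

    ``x`` is the column axis, ``y`` the row axis.  Returns a (5, H, W)
    array ordered (Hxx, Hyy, Hxy, lam1, lam2).
    """
    img = np.asarray(img, dtype=np.float64)
    _check_size(img, kernel)
    hxx = _gauss(img, kernel, (0, 2))
    hyy = _gauss(img, kernel, (2, 0))
    hxy = _gauss(img, kernel, (1, 1))
    # Eigenvalues of [[hxx, hxy], [hxy, hyy]] in closed form.
    tr = 0.5 * (hxx + hyy)
    det = np.sqrt(np.maximum((0.5 * (hxx - hyy)) ** 2 + hxy**2, 0.0))
    lam1 = tr + det
    lam2 = tr - det
    return np.stack([hxx, hyy, hxy, lam1, lam2])


def laplacian_plane(img: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Laplacian = Hxx + Hyy with the same Gaussian-derivative operator."""
    img = np.asarray(img, dtype=np.float64)
    _check_size(img, kernel)
    return _gauss(img, kernel, (0, 2)) + _gauss(img, kernel, (2, 0))


def local_std_plane(img: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Population standard deviation over the kernel x kernel window."""
    img = np.asarray(img, dtype=np.float64)
    _check_size(img, kernel)
    mean = ndimage.uniform_filter(img, size=kernel, mode="reflect")
    mean_sq = ndimage.uniform_filter(img**2, size=kernel, mode="reflect")
    return np.sqrt(np.maximum(mean_sq - mean**2, 0.0))


def circular_std_plane(img: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Circular standard deviation of gradient orientations in the window.

    Gradient orientations are axial (an edge at angle t is the same as
    t + pi), so the doubled-angle convention is used; each orientation is
    weighted by its gradient magnitude.  The dispersion is sqrt(-2 ln R)
    with R the weighted mean resultant length, capped at R = 1e-6; windows
    with zero total gradient magnitude yield 0.
    """
    img = np.asarray(img, dtype=np.float64)
    _check_size(img, kernel)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    theta2 = 2.0 * np.arctan2(gy, gx)
    c = ndimage.uniform_filter(mag * np.cos(theta2), size=kernel, mode="reflect")
    s = ndimage.uniform_filter(mag * np.sin(theta2), size=kernel, mode="reflect")
    w = ndimage.uniform_filter(mag, size=kernel, mode="reflect")
    out = np.zeros_like(img)
    eps = np.finfo(np.float64).tiny
    nz = w > eps
    rbar = np.zeros_like(img)
    rbar[nz] = np.hypot(c[nz], s[nz]) / w[nz]
    np.clip(rbar, 1e-6, 1.0, out=rbar)
    out[nz] = np.sqrt(-2.0 * np.log(rbar[nz]))
    return out


def _downscale(img: np.ndarray, factor: int) -> np.ndarray:
    """Area-average (block mean) downscale by an integer factor, reflect-
    padding the image to a multiple of the factor first."""
    if factor == 1:
        return img
    H, W = img.shape
    pad_h = (-H) % factor
    pad_w = (-W) % factor
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect")
    h, w = img.shape[0] // factor, img.shape[1] // factor
    return img.reshape(h, factor, w, factor).mean(axis=(1, 3))


def _upscale_nearest(img: np.ndarray, factor: int, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample by an integer factor, cropped to shape."""
    if factor == 1:
        return img[: shape[0], : shape[1]]
    big = np.repeat(np.repeat(img, factor, axis=0), factor, axis=1)
    return big[: shape[0], : shape[1]]


_PLANE_FUNCS = {
    "local_std": local_std_plane,
    "circ_std": circular_std_plane,
    "laplacian": laplacian_plane,
}


def _scale_planes(
    img: np.ndarray, names: tuple[str, ...], kernel: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if {"hxx", "hyy", "hxy", "eig1", "eig2"} & set(names):
        h = hessian_planes(img, kernel)
        out.update(zip(("hxx", "hyy", "hxy", "eig1", "eig2"), h))
    out["intensity"] = np.asarray(img, dtype=np.float64)
    for name, fn in _PLANE_FUNCS.items():
        if name in names:
            out[name] = fn(img, kernel)
    return out


def _scale_label(s: float) -> str:
    return {1.0: "1", 0.5: "1/2", 0.25: "1/4"}.get(s, f"{s:g}")


def extract_features(
    cimg: ClusterImage | np.ndarray, config: FeatureConfig | None = None
) -> FeatureStack:
    """Extract the multi-scale feature stack from a cluster image.

    Features are computed on the display channel (intensity-ranked cluster
    values, which are ordinal) rather than the nominal cluster ids.  For
    each scale the image is area-average downscaled, the per-scale planes
    computed, and the planes upsampled back to full resolution by nearest
    neighbour.  The default configuration emits exactly 24 planes.
    """
    if config is None:
        config = FeatureConfig()
    img = cimg.display if isinstance(cimg, ClusterImage) else np.asarray(cimg)
    img = img.astype(np.float64)
    H, W = img.shape
    planes: list[np.ndarray] = []
    names: list[str] = []
    for s in config.scales:
        factor = int(round(1.0 / s))
        small = _downscale(img, factor)
        if small.shape[0] < config.kernel or small.shape[1] < config.kernel:
            raise ValueError(
                f"image downscaled by {factor} is smaller than the kernel"
            )
        computed = _scale_planes(small, config.per_scale_features, config.kernel)
        for name in config.per_scale_features:
            planes.append(
                _upscale_nearest(computed[name], factor, (H, W)).astype(np.float32)
            )
            names.append(f"{name}@{_scale_label(s)}")
    return FeatureStack(planes=np.stack(planes), names=tuple(names))
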