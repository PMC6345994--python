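"""Acquisition quality metrics for transmission HSI microscopy.

Two-point lateral resolution under partially coherent illumination follows
Hopkins' treatment: the resolvable separation is ``R = A(sigma) * lambda /
NA_obj`` where ``sigma = NA_ill / NA_obj`` is the coherence ratio and
``A(sigma)`` the two-point resolution factor, which plateaus at 0.82 in
the nearly coherent regime (sigma <= 0.2) and falls toward the incoherent
Rayleigh value 0.61 as sigma grows.  The factor table between those limits
is an approximate monotone reading of the Hopkins-Barham curve, linearly
interpolated; only the coherent plateau is exercised by the default
instrument configuration (sigma = 0.063 / 0.45 = 0.14).

Illumination stability is summarized from repeated specimen-free
illumination images: per-pixel maximum temporal deviation as a percent of
the global mean intensity (temporal fluctuation) and smoothed peak-to-peak
spatial variation as a percent of the mean (spatial non-uniformity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: (sigma, A) knots of the two-point resolution factor; linear in between.
HOPKINS_FACTOR_TABLE = (
    (0.0, 0.82),
    (0.2, 0.82),
    (0.5, 0.77),
    (1.0, 0.69),
    (1.5, 0.63),
    (2.0, 0.61),
)


@dataclass(frozen=True)
class OpticalConfig:
    """The instrument's optical parameters.

    The default objective NA (0.45) is the manufacturer value of the 20x
    semi-apochromat used; the illumination NA (0.063) is the minimum iris
    aperture diaphragm setting.
    """

    na_objective: float = 0.45
    na_illumination: float = 0.063
    wavelength: float = 550.0  # nm

    def __post_init__(self) -> None:
        if not (0 < self.na_illumination <= self.na_objective < 1.5):
            raise ValueError(
                "require 0 < na_illumination <= na_objective < 1.5"
            )


@dataclass
class StabilityReport:
    fluctuation_fractions: dict[float, float]
    nonuniformity_percent: float | None = None


def coherence_ratio(config: OpticalConfig) -> float:
    """sigma = NA_illumination / NA_objective (0 = coherent limit)."""
    if config.na_objective == 0:
        raise ValueError("objective NA must be non-zero")
    return config.na_illumination / config.na_objective


def hopkins_resolution(config: OpticalConfig) -> float:
    """Two-point lateral resolution in micrometres: A(sigma) * lambda / NA."""
    if not (350.0 <= config.wavelength <= 900.0):
        raise ValueError("wavelength must be in [350, 900] nm")
    sigma = coherence_ratio(config)
    sigmas = np.array([s for s, _ in HOPKINS_FACTOR_TABLE])
    factors = np.array([a for _, a in HOPKINS_FACTOR_TABLE])
    if sigma < sigmas[0] or sigma > sigmas[-1]:
        raise ValueError(f"coherence ratio {sigma:.3f} outside the factor table")
    a = float(np.interp(sigma, sigmas, factors))
    return a * (config.wavelength / 1000.0) / config.na_objective


def temporal_fluctuation(
    images: list[np.ndarray], tolerances: list[float]
) -> StabilityReport:
    """Fraction of pixels whose maximum temporal deviation stays within each
    tolerance (percent of the global mean intensity at this wavelength)."""
    if len(images) < 2:
        raise ValueError("need at least 2 repeated illumination images")
    stack = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    if any(im.shape != stack[0].shape for im in stack):
        raise ValueError("all images must share the same shape")
    global_mean = stack.mean()
    if global_mean == 0:
        raise ValueError("zero mean intensity")
    dev = np.abs(stack - stack.mean(axis=0)).max(axis=0)
    dev_percent = 100.0 * dev / global_mean
    fractions = {
        float(t): float(np.mean(dev_percent <= t)) for t in sorted(tolerances)
    }
    return StabilityReport(fluctuation_fractions=fractions)


def spatial_nonuniformity(image: np.ndarray, median_size: int = 5) -> float:
    """Smoothed peak-to-peak spatial variation as percent of the mean.

    A median filter (default 5x5) suppresses shot noise before taking
    (max - min) / mean * 100.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    mean = img.mean()
    if mean == 0:
        raise ValueError("zero mean intensity")
    smooth = ndimage.median_filter(img, size=median_size, mode="reflect")
    return float(100.0 * (smooth.max() - smooth.min()) / mean)
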