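"""Seeded generator of synthetic hyperspectral scenes with ground truth.

The generator emulates transmission hyperspectral images of differentiated
neural stem cell cultures: elliptical neuronal and glial cell bodies with a
bright center zone and a darker edge band, thin widened random-walk
processes attached to the bodies, and a flat external background.  Each
pixel class carries a characteristic 25-band transmittance spectrum
(450-690 nm, 10-nm pitch); the raw object stack is synthesized as

    O = round(signature * illumination * (flat_level - dark_level)
              + dark_level + noise)

together with a matching dark stack ``D = dark_level + noise`` and a
flat-field reference ``F = dark_level + illumination * (flat_level -
dark_level) + noise``, so that flat-field correction recovers the
signature spectra exactly in the noise-free case and cancels the smooth
multiplicative illumination field.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .hsidata import (
    EXTERNAL,
    GLIA_BODY,
    IGNORE,
    NEURON_BODY,
    PROCESS,
    HyperStack,
    LabelMap,
    WavelengthGrid,
)

#: The analysis wavelength grid: 25 bands, 450-690 nm at 10-nm pitch.
ANALYSIS_GRID = WavelengthGrid.from_range(450.0, 690.0, 10.0)

_PLACEMENT_RETRIES = 200
_MARGIN = 2  # px clearance between placed objects


@dataclass(frozen=True)
class SpectralSignature:
    """A named 25-band transmittance spectrum on the FFC scale (~0.2-1.6)."""

    name: str
    spectrum: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectrum, dtype=float)
        if spec.shape != (len(ANALYSIS_GRID),):
            raise ValueError("signature spectrum must have 25 bands")
        if np.any(spec <= 0):
            raise ValueError("signature spectrum must be strictly positive")
        object.__setattr__(self, "spectrum", spec)


def default_signature_bank() -> list[SpectralSignature]:
    """Six signatures emulating the observed subcellular spectral structure.

    Neuronal cell bodies carry a bright center spectrum ``N_high`` and a dark
    edge spectrum ``N_low`` (the brightest and darkest spectra in the scene);
    glial bodies carry ``G_high`` / ``G_low``; processes a single moderate
    spectrum; and the external region sits flat near 1.0 (a specimen-free
    pixel transmits the full illumination).  The glial center spectrum rises
    toward long wavelengths relative to the process spectrum, giving the
    classifier a wavelength-specific cue and not just a brightness cue.
    """
    t = (ANALYSIS_GRID.wavelengths - 450.0) / 240.0  # 0 .. 1 over the grid
    bank = [
        SpectralSignature("N_high", 1.35 + 0.05 * t),
        SpectralSignature("N_low", 0.55 + 0.05 * t),
        SpectralSignature("G_high", 1.10 + 0.25 * t),
        SpectralSignature("G_low", 0.70 + 0.05 * t),
        SpectralSignature("P_process", 0.88 + 0.02 * t),
        SpectralSignature("E_external", np.full(len(ANALYSIS_GRID), 1.0)),
    ]
    return bank


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Counts are sensor counts of a 12-bit camera stored in 16 bits.  The
    defaults are the desk-scale study conditions: 256 x 256 px scenes with a
    handful of cells, a 10% peak-to-peak smooth illumination field (within
    the 3.5-14.1% non-uniformity observed on the real instrument) and
    additive Gaussian sensor noise with s.d. 2% of the dynamic range.
    """

    height: int = 256
    width: int = 256
    n_neurons: int = 5
    n_glia: int = 2
    neuron_radius: tuple[float, float] = (8.0, 14.0)
    glia_radius: tuple[float, float] = (14.0, 22.0)
    process_width: tuple[float, float] = (2.0, 3.0)
    process_length: tuple[int, int] = (30, 60)
    processes_per_body: tuple[int, int] = (1, 2)
    edge_band: int = 3
    illumination_amplitude: float = 0.10
    illumination_order: int = 2
    dark_level: float = 200.0
    flat_level: float = 2400.0
    noise_sd: float = 44.0
    n_ignore_blobs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("scene dimensions must be >= 64")
        if self.n_neurons < 0 or self.n_glia < 0:
            raise ValueError("object counts must be >= 0")
        if self.flat_level <= self.dark_level:
            raise ValueError("flat_level must exceed dark_level")
        if self.dark_level < 0 or self.noise_sd < 0:
            raise ValueError("count levels must be >= 0")


@dataclass
class SceneObject:
    """One ground-truth object: a cell body or a process."""

    object_id: int
    class_code: int
    pixels: np.ndarray  # (n, 2) row/col indices


@dataclass
class SceneTruth:
    labels: LabelMap
    objects: list[SceneObject]


def _illumination_field(
    rng: np.random.Generator, height: int, width: int, amplitude: float, order: int
) -> np.ndarray:
    """Smooth multiplicative field: low-order polynomial, mean ~1,
    peak-to-peak equal to ``amplitude``."""
    if amplitude <= 0:
        return np.ones((height, width))
    v, u = np.meshgrid(
        np.linspace(-1.0, 1.0, height), np.linspace(-1.0, 1.0, width), indexing="ij"
    )
    poly = np.zeros((height, width))
    for p in range(order + 1):
        for q in range(order + 1 - p):
            if p + q == 0:
                continue
            poly += rng.normal() * (u**p) * (v**q)
    span = poly.max() - poly.min()
    if span == 0:
        return np.ones((height, width))
    poly = (poly - poly.min()) / span  # [0, 1]
    return 1.0 - amplitude / 2.0 + amplitude * poly


def _place_bodies(
    rng: np.random.Generator, config: SceneConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, np.ndarray, tuple[float, float]]]]:
    """Place non-overlapping elliptical bodies; returns (labels, sig_idx, bodies)."""
    H, W = config.height, config.width
    labels = np.full((H, W), EXTERNAL, dtype=np.uint8)
    taken = np.zeros((H, W), dtype=bool)
    bodies: list[tuple[int, np.ndarray, tuple[float, float]]] = []
    specs = [(NEURON_BODY, config.neuron_radius)] * config.n_neurons
    specs += [(GLIA_BODY, config.glia_radius)] * config.n_glia
    margin_struct = disk(_MARGIN)
    for class_code, (r_lo, r_hi) in specs:
        for _ in range(_PLACEMENT_RETRIES):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            rot = rng.uniform(0.0, np.pi)
            rmax = max(a, b)
            cy = rng.uniform(rmax + 1, H - rmax - 1)
            cx = rng.uniform(rmax + 1, W - rmax - 1)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(H, W), rotation=rot)
            if rr.size == 0 or taken[rr, cc].any():
                continue
            mask = np.zeros((H, W), dtype=bool)
            mask[rr, cc] = True
            labels[mask] = class_code
            taken |= ndimage.binary_dilation(mask, structure=margin_struct)
            bodies.append((class_code, mask, (cy, cx)))
            break
        else:
            raise RuntimeError(
                "could not place a cell body within the retry limit; "
                "reduce object counts or radii"
            )
    return labels, taken, bodies


def _walk_process(
    rng: np.random.Generator,
    start: tuple[float, float],
    direction: float,
    length: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Meandering unit-step random walk; returns a boolean path mask."""
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    y, x = start
    ang = direction
    for _ in range(length):
        ang += rng.normal(0.0, 0.3)
        y += np.sin(ang)
        x += np.cos(ang)
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < H and 0 <= ix < W:
            mask[iy, ix] = True
    return mask


def generate_scene(
    config: SceneConfig,
    bank: list[SpectralSignature] | None = None,
) -> tuple[HyperStack, HyperStack, HyperStack, SceneTruth]:
    """Generate one scene: raw object stack O, dark D, flat F and truth.

    Bodies are ellipses whose interior (eroded by ``edge_band``) carries the
    high signature and whose rim carries the low signature; each body emits
    1-2 widened random-walk processes labelled as the combined process
    class.  Deterministic given ``config.seed``.
    """
    if bank is None:
        bank = default_signature_bank()
    sig_index = {s.name: i for i, s in enumerate(bank)}
    spectra = np.stack([s.spectrum for s in bank])  # (n_sig, 25)
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width

    labels, taken, bodies = _place_bodies(rng, config)
    sig_map = np.full((H, W), sig_index["E_external"], dtype=np.int8)
    objects: list[SceneObject] = []
    obj_id = 0

    zone = {
        NEURON_BODY: ("N_high", "N_low"),
        GLIA_BODY: ("G_high", "G_low"),
    }
    edge_struct = disk(config.edge_band)
    for class_code, mask, _center in bodies:
        center = ndimage.binary_erosion(mask, structure=edge_struct)
        hi, lo = zone[class_code]
        sig_map[mask] = sig_index[lo]
        if center.any():
            sig_map[center] = sig_index[hi]
        rr, cc = np.nonzero(mask)
        objects.append(SceneObject(obj_id, class_code, np.column_stack([rr, cc])))
        obj_id += 1

    # Processes: widened random walks leaving each body outward.
    for class_code, mask, (cy, cx) in bodies:
        boundary = mask & ~ndimage.binary_erosion(mask)
        brr, bcc = np.nonzero(boundary)
        n_proc = int(
            rng.integers(config.processes_per_body[0], config.processes_per_body[1] + 1)
        )
        for _ in range(n_proc):
            k = int(rng.integers(0, brr.size))
            sy, sx = float(brr[k]), float(bcc[k])
            outward = np.arctan2(sy - cy, sx - cx)
            length = int(rng.integers(config.process_length[0], config.process_length[1] + 1))
            width = rng.uniform(*config.process_width)
            path = _walk_process(rng, (sy, sx), outward, length, (H, W))
            radius = max(1, int(round(width / 2.0)))
            thick = ndimage.binary_dilation(path, structure=disk(radius))
            proc_mask = thick & (labels == EXTERNAL)
            if not proc_mask.any():
                continue
            labels[proc_mask] = PROCESS
            sig_map[proc_mask] = sig_index["P_process"]
            rr, cc = np.nonzero(proc_mask)
            objects.append(SceneObject(obj_id, PROCESS, np.column_stack([rr, cc])))
            obj_id += 1

    # Optional ignore blobs on the external region (exercise masking paths).
    for _ in range(config.n_ignore_blobs):
        r = rng.uniform(4, 8)
        cy = rng.uniform(r + 1, H - r - 1)
        cx = rng.uniform(r + 1, W - r - 1)
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(H, W))
        blob = np.zeros((H, W), dtype=bool)
        blob[rr, cc] = True
        blob &= labels == EXTERNAL
        labels[blob] = IGNORE

    illum = _illumination_field(
        rng, H, W, config.illumination_amplitude, config.illumination_order
    )
    dyn = config.flat_level - config.dark_level
    cube = spectra[sig_map]  # (H, W, 25)
    cube = np.moveaxis(cube, -1, 0)  # (25, H, W)
    signal = cube * illum[None] * dyn + config.dark_level

    def _counts(arr: np.ndarray) -> np.ndarray:
        if config.noise_sd > 0:
            arr = arr + rng.normal(0.0, config.noise_sd, size=arr.shape)
        return np.clip(np.rint(arr), 0, 4095).astype(np.uint16)

    n_bands = len(ANALYSIS_GRID)
    O = _counts(signal)
    D = _counts(np.full((n_bands, H, W), config.dark_level))
    F = _counts(np.broadcast_to(illum[None] * dyn + config.dark_level, (n_bands, H, W)).copy())

    truth = SceneTruth(labels=LabelMap(labels), objects=objects)
    stacks = (
        HyperStack(O, ANALYSIS_GRID, role="raw_object"),
        HyperStack(D, ANALYSIS_GRID, role="dark"),
        HyperStack(F, ANALYSIS_GRID, role="flat"),
    )
    return (*stacks, truth)


def generate_dataset(
    n_images: int,
    base_config: SceneConfig,
    base_seed: int,
    bank: list[SpectralSignature] | None = None,
) -> list[tuple[HyperStack, HyperStack, HyperStack, SceneTruth]]:
    """Generate ``n_images`` scenes with seeds ``base_seed + i``.

    Every scene contains at least one neuronal and one glial cell body (the
    evaluation design requires both cell types in every image), so
    configurations with zero neurons or glia are rejected.
    """
    if n_images < 2:
        raise ValueError("a dataset needs at least 2 images")
    if base_config.n_neurons < 1 or base_config.n_glia < 1:
        raise ValueError("every scene must contain >= 1 neuron and >= 1 glial cell")
    return [
        generate_scene(replace(base_config, seed=base_seed + i), bank=bank)
        for i in range(n_images)
    ]
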