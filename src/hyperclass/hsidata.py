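"""Data model and I/O for hyperspectral image stacks.

A hyperspectral acquisition consists of a raw object stack ``O`` (one page
per wavelength band), a dark image ``D`` (light path shuttered) and a
flat-field reference ``F`` (illumination without a specimen), all taken with
matched exposure settings.  Flat-field correction

    FFC = (O - D) / (F - D)

removes the camera dark offset and the spatial non-uniformity of the
illumination, putting every pixel spectrum on a dimensionless transmittance
scale.  Downstream analysis (spectral clustering, classification) runs on a
25-band subset of the corrected stack.

Stacks are band-major ``(band, row, column)``; row 0 is the image top and
pixel indices are 0-based.  Raw data are 16-bit unsigned counts (the camera
is 12-bit); corrected data are 32-bit reals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

log = logging.getLogger(__name__)

# Class codes of the ground-truth / prediction label maps.
EXTERNAL = 0
NEURON_BODY = 1
GLIA_BODY = 2
PROCESS = 3
IGNORE = 255

#: Classes that take part in training and evaluation (IGNORE is excluded).
CLASS_CODES = (EXTERNAL, NEURON_BODY, GLIA_BODY, PROCESS)
CELL_CLASS_CODES = (NEURON_BODY, GLIA_BODY, PROCESS)

CLASS_NAMES = {
    EXTERNAL: "external",
    NEURON_BODY: "neuronal cell body",
    GLIA_BODY: "glial cell body",
    PROCESS: "process",
    IGNORE: "ignore",
}

ROLES = ("raw_object", "dark", "flat", "corrected")

_WL_MIN, _WL_MAX = 350.0, 900.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nm (strictly increasing)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() < _WL_MIN or wl.max() > _WL_MAX:
            raise ValueError(
                f"wavelengths must lie in [{_WL_MIN:g}, {_WL_MAX:g}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        """Inclusive arithmetic grid, e.g. ``from_range(450, 690, 10)`` -> 25 bands."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self) -> int:  # frozen dataclass with ndarray payload
        return hash(self.wavelengths.tobytes())


@dataclass
class HyperStack:
    """A bands x H x W image cube with an explicit wavelength grid.

    ``invalid`` is an optional H x W boolean mask of pixels whose flat-field
    correction was undefined (F - D <= 0 in some band); it propagates into
    downstream ignore handling.
    """

    data: np.ndarray
    grid: WavelengthGrid
    role: str = "raw_object"
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("stack data must be 3-D (band, row, column)")
        if data.shape[0] != len(self.grid):
            raise ValueError(
                f"stack has {data.shape[0]} bands but grid has {len(self.grid)}"
            )
        if data.shape[1] < 1 or data.shape[2] < 1:
            raise ValueError("stack spatial dimensions must be >= 1")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role != "corrected" and np.any(data < 0):
            raise ValueError("raw/dark/flat intensities must be non-negative")
        self.data = data
        if self.invalid is not None:
            inv = np.asarray(self.invalid, dtype=bool)
            if inv.shape != data.shape[1:]:
                raise ValueError("invalid mask shape must match (H, W)")
            self.invalid = inv

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """H x W class-coded ground truth / prediction image.

    Codes: 0 external, 1 neuronal cell body, 2 glial cell body, 3 process,
    255 ignore (e.g. double-positive / double-negative cells excluded from
    training and evaluation).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label map must be 2-D")
        codes = np.unique(lab)
        allowed = set(CLASS_CODES) | {IGNORE}
        bad = [int(c) for c in codes if int(c) not in allowed]
        if bad:
            raise ValueError(f"label map contains unknown class codes {bad}")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: str | Path, metadata_path: str | Path | None) -> Path:
    if metadata_path is not None:
        return Path(metadata_path)
    return Path(str(path) + ".json")


def write_stack(
    stack: HyperStack,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a stack as a multi-page TIFF (one page per band) + JSON sidecar.

    Raw/dark/flat stacks are stored as 16-bit unsigned integers, corrected
    stacks as 32-bit floats (lossless for float32 data).
    """
    path = Path(path)
    if stack.n_bands < 1:  # unreachable through the constructor; belt-and-braces
        raise ValueError("cannot write a stack with no bands")
    if stack.role == "corrected":
        data = stack.data.astype(np.float32)
    else:
        if np.any(stack.data > np.iinfo(np.uint16).max):
            raise ValueError("raw counts exceed the 16-bit range")
        data = stack.data.astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "role": stack.role,
        "wavelengths_nm": [float(w) for w in stack.grid.wavelengths],
        "exposure_note": "per-band exposures matched across O/D/F",
    }
    _sidecar_path(path, metadata_path).write_text(json.dumps(meta, indent=1))


def read_stack(
    path: str | Path, metadata_path: str | Path | None = None
) -> HyperStack:
    """Read a multi-page TIFF stack with its JSON wavelength sidecar."""
    meta = json.loads(_sidecar_path(path, metadata_path).read_text())
    grid = WavelengthGrid(np.asarray(meta["wavelengths_nm"], dtype=float))
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(grid):
        raise ValueError(
            f"file has {data.shape[0]} pages but metadata lists {len(grid)} wavelengths"
        )
    return HyperStack(data=data, grid=grid, role=meta.get("role", "raw_object"))


def write_labelmap(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a single-page 8-bit PNG or TIFF (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels.labels)
    else:
        iio.imwrite(path, labels.labels)


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return LabelMap(np.asarray(arr, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Processing


def flat_field_correct(O: HyperStack, D: HyperStack, F: HyperStack) -> HyperStack:
    """Per-pixel, per-band flat-field correction FFC = (O - D) / (F - D).

    Pixels where F - D <= 0 in any band cannot be corrected (a dead or noisy
    sensor element); their values are set to 0 and they are flagged in the
    result's ``invalid`` mask rather than raising, so isolated bad pixels do
    not abort a session.  The count of flagged pixels is logged.
    """
    if O.shape != D.shape or O.shape != F.shape:
        raise ValueError("O, D and F must share the same shape")
    if not (O.grid == D.grid and O.grid == F.grid):
        raise ValueError("O, D and F must share the same wavelength grid")
    num = O.data.astype(np.float64) - D.data.astype(np.float64)
    den = F.data.astype(np.float64) - D.data.astype(np.float64)
    bad = den <= 0
    ffc = np.zeros_like(num, dtype=np.float32)
    np.divide(num, den, out=ffc, where=~bad, casting="unsafe")
    ffc[bad] = 0.0
    invalid = bad.any(axis=0)
    n_bad = int(invalid.sum())
    if n_bad:
        log.warning("flat-field correction: %d invalid pixels (F - D <= 0)", n_bad)
    return HyperStack(data=ffc, grid=O.grid, role="corrected", invalid=invalid)


def select_bands(stack: HyperStack, requested: WavelengthGrid) -> HyperStack:
    """Subset a stack to the requested wavelengths (exact integer-nm match).

    The study acquires 63 bands at 420-730 nm (5-nm pitch) and analyses the
    25-band subset 450-690 nm at a 10-nm pitch.  No interpolation is done;
    a wavelength absent from the stack raises an error naming it.
    """
    have = stack.grid.wavelengths
    idx = []
    for w in requested.wavelengths:
        hit = np.nonzero(have == w)[0]
        if hit.size == 0:
            raise ValueError(f"wavelength {w:g} nm not present in the stack grid")
        idx.append(int(hit[0]))
    return HyperStack(
        data=stack.data[idx],
        grid=requested,
        role=stack.role,
        invalid=stack.invalid,
    )
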