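"""Shared domain containers for Raman hyperspectral tissue maps.

A hyperspectral map is a regular spatial grid of Raman spectra: every pixel
carries a full spectrum sampled on a common wavenumber axis (cm^-1).  The
seven-class coding used throughout the package is fixed: class 0 is
stroma/empty background, classes 1-6 are the nucleus and cytoplasm of the
three pancreatic-cancer groups (AVAC, cPDAC, IPMC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralMap",
    "ClassScheme",
    "DEFAULT_SCHEME",
    "MaskStats",
    "mask_stats",
    "canonical_axis",
    "acquisition_axis",
    "validate_mask",
    "UNANNOTATED",
]

#: Mask value marking a pixel without a ground-truth annotation.
UNANNOTATED = -1

#: Analysis (fingerprint) window limits in cm^-1.
TRIM_LO = 650.0
TRIM_HI = 1800.0

#: Canonical preprocessed spectral length (uniform grid over [650, 1800]).
CANONICAL_LEN = 320

#: Acquisition window limits in cm^-1.
ACQ_LO = 600.0
ACQ_HI = 1900.0


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing axis of positive wavenumbers (cm^-1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis must be a 1-D array with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("axis contains non-finite values")
        if np.any(values <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def canonical_axis(lo: float = TRIM_LO, hi: float = TRIM_HI, n: int = CANONICAL_LEN) -> WavenumberAxis:
    """The canonical preprocessed grid: ``n`` uniform points on [lo, hi]."""
    return WavenumberAxis(np.linspace(lo, hi, n))


def acquisition_axis(lo: float = ACQ_LO, hi: float = ACQ_HI, step: float = 2.0) -> WavenumberAxis:
    """A raw-instrument style axis covering the acquisition window."""
    n = int(round((hi - lo) / step)) + 1
    return WavenumberAxis(np.linspace(lo, hi, n))


@dataclass
class Spectrum:
    """A single Raman spectrum: intensities on a shared wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be 1-D")
        if self.intensity.size != len(self.axis):
            raise ValueError(
                f"intensity length {self.intensity.size} != axis length {len(self.axis)}"
            )

    def __len__(self) -> int:
        return int(self.intensity.size)


@dataclass(frozen=True)
class ClassScheme:
    """The fixed ordered coding of the seven tissue classes (indices 0-6)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != 7:
            raise ValueError("a class scheme must have exactly 7 labels")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_SCHEME = ClassScheme(
    (
        "stroma/empty",
        "AVAC nucleus",
        "AVAC cytoplasm",
        "cPDAC nucleus",
        "cPDAC cytoplasm",
        "IPMC nucleus",
        "IPMC cytoplasm",
    )
)


def validate_mask(mask: np.ndarray, n_classes: int = 7) -> np.ndarray:
    """Check a label mask holds only {-1, 0..n_classes-1}; return as int array."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        arr = np.asarray(mask, dtype=float)
        if not np.array_equal(arr, np.round(arr)):
            raise ValueError("mask values must be integers")
        mask = arr.astype(int)
    bad = (mask < UNANNOTATED) | (mask >= n_classes)
    if np.any(bad):
        raise ValueError(
            f"mask contains labels outside {{-1, 0..{n_classes - 1}}}: "
            f"{np.unique(mask[bad])}"
        )
    return mask.astype(np.int64)


@dataclass
class HyperspectralMap:
    """A height x width grid of spectra plus the shared axis.

    ``cube`` has shape (height, width, len(axis)).  ``mask`` is an optional
    per-pixel class annotation with -1 marking unannotated pixels.  Pixel
    (row, col) sits at x = col * step_um, y = row * step_um with row 0 at the
    top, matching the usual image-plotting convention.
    """

    axis: WavenumberAxis
    cube: np.ndarray
    step_um: float = 1.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must have shape (height, width, n_points)")
        if self.cube.shape[2] != len(self.axis):
            raise ValueError(
                f"cube spectral length {self.cube.shape[2]} != axis length {len(self.axis)}"
            )
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.mask is not None:
            self.mask = validate_mask(self.mask)
            if self.mask.shape != self.cube.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != map shape {self.cube.shape[:2]}"
                )

    @property
    def height(self) -> int:
        return int(self.cube.shape[0])

    @property
    def width(self) -> int:
        return int(self.cube.shape[1])

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (x_um, y_um) grids, each of shape (height, width)."""
        y, x = np.mgrid[0 : self.height, 0 : self.width]
        return x * self.step_um, y * self.step_um

    def spectra(self) -> np.ndarray:
        """Flattened view of the cube, shape (n_pixels, n_points), row-major."""
        return self.cube.reshape(self.n_pixels, len(self.axis))

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col])


@dataclass
class MaskStats:
    """Per-class pixel counts and the annotated fraction of a label mask."""

    counts: Mapping[int, int]
    annotated: int
    unannotated: int
    total: int

    @property
    def fraction(self) -> float:
        return self.annotated / self.total if self.total else 0.0


def mask_stats(mask: np.ndarray, n_classes: int = 7) -> MaskStats:
    """Count pixels per class and the annotated fraction.

    Counts (including the -1 unannotated bucket) always sum to the total
    pixel count of the mask.
    """
    mask = validate_mask(mask, n_classes)
    total = int(mask.size)
    values, counts = np.unique(mask, return_counts=True)
    by_class = {int(v): int(c) for v, c in zip(values, counts) if v != UNANNOTATED}
    unannotated = total - sum(by_class.values())
    return MaskStats(
        counts=by_class,
        annotated=total - unannotated,
        unannotated=unannotated,
        total=total,
    )
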