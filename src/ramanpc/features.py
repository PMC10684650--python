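"""Band-integral features and the diagnostic ratios.

Three spectroscopic ratios summarize the chemistry that separates the
pancreatic-cancer subtypes:

* DNA methylation — delta(CH2, CH3) 1360-1420 cm^-1 over nu_s(PO2-)
  1050-1150 cm^-1;
* protein beta-sheet — beta-sheet amide III 1218-1228 cm^-1 over total
  amide I 1514-1750 cm^-1;
* protein random coil — random-coil amide I 1640-1664 cm^-1 over total
  amide I 1514-1750 cm^-1.

"Summed intensity" is a plain sum of grid-point intensities inside the
closed window (trapezoidal integration is available via ``method="trapz"``).
The 9-component per-spectrum record for the second-stage classifier is, in
order: DNA sum, methylated-DNA sum, methylation ratio, total-protein sum,
beta-sheet sum, beta-sheet ratio, random-coil sum, random-coil ratio, and
the first-stage CNN class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Spectrum, WavenumberAxis

__all__ = [
    "BandWindow",
    "DNA_WINDOW",
    "METHYL_WINDOW",
    "BETA_SHEET_WINDOW",
    "AMIDE_I_WINDOW",
    "RANDOM_COIL_WINDOW",
    "EmptyWindowError",
    "band_sum",
    "methylation_ratio",
    "beta_sheet_ratio",
    "random_coil_ratio",
    "RatioFeatures",
    "build_feature_record",
    "feature_matrix",
    "FEATURE_NAMES",
]


class EmptyWindowError(ValueError):
    """Raised when no grid point of the axis falls inside a band window."""


@dataclass(frozen=True)
class BandWindow:
    """A closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("window lo must be < hi")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


DNA_WINDOW = BandWindow(1050.0, 1150.0, "nu_s(PO2-) DNA backbone")
METHYL_WINDOW = BandWindow(1360.0, 1420.0, "delta(CH2, CH3) methylated DNA")
BETA_SHEET_WINDOW = BandWindow(1218.0, 1228.0, "beta-sheet amide III")
AMIDE_I_WINDOW = BandWindow(1514.0, 1750.0, "total amide I")
RANDOM_COIL_WINDOW = BandWindow(1640.0, 1664.0, "random-coil amide I")

FEATURE_NAMES = (
    "dna_sum",
    "methylated_dna_sum",
    "methylation_ratio",
    "total_protein_sum",
    "beta_sheet_sum",
    "beta_sheet_ratio",
    "random_coil_sum",
    "random_coil_ratio",
    "cnn_class",
)


def _eps(axis_len: int, max_intensity: float) -> float:
    return 1e-12 * axis_len * max(max_intensity, 1.0)


def band_sum(s: Spectrum, window: BandWindow, method: str = "sum") -> float:
    """Summed intensity at grid points inside the closed window."""
    m = window.mask(s.axis.values)
    if not m.any():
        raise EmptyWindowError(
            f"no grid point inside [{window.lo}, {window.hi}] cm^-1"
        )
    if method == "trapz":
        return float(np.trapezoid(s.intensity[m], s.axis.values[m]))
    return float(np.sum(s.intensity[m]))


def _ratio(s: Spectrum, num: BandWindow, den: BandWindow) -> tuple[float, bool]:
    numerator = band_sum(s, num)
    denominator = band_sum(s, den)
    eps = _eps(len(s), float(np.max(np.abs(s.intensity), initial=0.0)))
    if abs(denominator) < eps:
        return 0.0, False  # flagged undefined, reported as 0 by convention
    return numerator / denominator, True


def methylation_ratio(s: Spectrum) -> float:
    """DNA-methylation ratio: sum(1360-1420) / sum(1050-1150)."""
    return _ratio(s, METHYL_WINDOW, DNA_WINDOW)[0]


def beta_sheet_ratio(s: Spectrum) -> float:
    """Beta-sheet ratio: sum(1218-1228) / sum(1514-1750)."""
    return _ratio(s, BETA_SHEET_WINDOW, AMIDE_I_WINDOW)[0]


def random_coil_ratio(s: Spectrum) -> float:
    """Random-coil ratio: sum(1640-1664) / sum(1514-1750)."""
    return _ratio(s, RANDOM_COIL_WINDOW, AMIDE_I_WINDOW)[0]


@dataclass(frozen=True)
class RatioFeatures:
    """The ordered 9-component record fed to the second-stage classifier."""

    dna_sum: float
    methylated_dna_sum: float
    methylation_ratio: float
    total_protein_sum: float
    beta_sheet_sum: float
    beta_sheet_ratio: float
    random_coil_sum: float
    random_coil_ratio: float
    cnn_class: int
    ratios_defined: tuple[bool, bool, bool] = (True, True, True)  # not a component

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.dna_sum,
                self.methylated_dna_sum,
                self.methylation_ratio,
                self.total_protein_sum,
                self.beta_sheet_sum,
                self.beta_sheet_ratio,
                self.random_coil_sum,
                self.random_coil_ratio,
                float(self.cnn_class),
            ]
        )


def build_feature_record(s: Spectrum, cnn_class: int) -> RatioFeatures:
    """Assemble the 9-component record for one preprocessed spectrum."""
    if not (0 <= int(cnn_class) <= 6):
        raise ValueError("cnn_class must be in 0..6")
    meth, meth_ok = _ratio(s, METHYL_WINDOW, DNA_WINDOW)
    beta, beta_ok = _ratio(s, BETA_SHEET_WINDOW, AMIDE_I_WINDOW)
    coil, coil_ok = _ratio(s, RANDOM_COIL_WINDOW, AMIDE_I_WINDOW)
    return RatioFeatures(
        dna_sum=band_sum(s, DNA_WINDOW),
        methylated_dna_sum=band_sum(s, METHYL_WINDOW),
        methylation_ratio=meth,
        total_protein_sum=band_sum(s, AMIDE_I_WINDOW),
        beta_sheet_sum=band_sum(s, BETA_SHEET_WINDOW),
        beta_sheet_ratio=beta,
        random_coil_sum=band_sum(s, RANDOM_COIL_WINDOW),
        random_coil_ratio=coil,
        cnn_class=int(cnn_class),
        ratios_defined=(meth_ok, beta_ok, coil_ok),
    )


def feature_matrix(
    X: np.ndarray, axis: WavenumberAxis, cnn_classes: np.ndarray
) -> np.ndarray:
    """Vectorized record assembly: (n, p) spectra -> (n, 9) feature rows."""
    X = np.asarray(X, dtype=float)
    cnn_classes = np.asarray(cnn_classes)
    if X.shape[0] != cnn_classes.shape[0]:
        raise ValueError("X and cnn_classes disagree on the number of spectra")
    if np.any((cnn_classes < 0) | (cnn_classes > 6)):
        raise ValueError("cnn_classes must be in 0..6")
    wn = axis.values
    sums = {}
    for key, win in (
        ("dna", DNA_WINDOW),
        ("meth", METHYL_WINDOW),
        ("beta", BETA_SHEET_WINDOW),
        ("amide1", AMIDE_I_WINDOW),
        ("coil", RANDOM_COIL_WINDOW),
    ):
        m = win.mask(wn)
        if not m.any():
            raise EmptyWindowError(f"no grid point inside [{win.lo}, {win.hi}] cm^-1")
        sums[key] = X[:, m].sum(axis=1)
    eps = _eps(len(axis), float(np.max(np.abs(X), initial=0.0)))
    dna_safe = np.where(np.abs(sums["dna"]) < eps, np.inf, sums["dna"])
    amide_safe = np.where(np.abs(sums["amide1"]) < eps, np.inf, sums["amide1"])
    out = np.column_stack(
        [
            sums["dna"],
            sums["meth"],
            sums["meth"] / dna_safe,
            sums["amide1"],
            sums["beta"],
            sums["beta"] / amide_safe,
            sums["coil"],
            sums["coil"] / amide_safe,
            cnn_classes.astype(float),
        ]
    )
    return out
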