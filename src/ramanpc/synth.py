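"""Synthetic Raman tissue-map generator.

Real tumor-tissue hyperspectral maps are rarely shareable, so this module
fabricates maps whose seven class signatures carry the molecular contrasts
reported for pancreatic-cancer subtypes:

* AVAC nuclei — elevated DNA/histone methylation, read out through the
  delta(CH2, CH3) region (1391, 1489, 1280 cm^-1) and DNA-backbone bands
  (879, 1070, 1128 cm^-1); hypermethylation is *local*, so only a fraction
  of AVAC-nucleus pixels draw from a high-methylation signature variant.
* cPDAC nuclei — beta-sheet-rich nuclear proteins: amide I centred at
  1628 cm^-1 and a strong beta-sheet amide III band (1218-1228 cm^-1).
* IPMC nuclei — turns/random-coil-rich proteins: amide I centred at
  1650 cm^-1.
* Cytoplasm classes — shared protein bands (Phe 1004, CH2/CH3 bend
  ~1450, amide III 1230-1340) with subtype accents: Tyr 1170 and amide II
  1540 (IPMC), C-C6H5 Phe/Trp 1208 (cPDAC), methyl/methylene 1448, 1299,
  1378 and reduced cytochrome C 1128 (AVAC and IPMC).

Spectra are sums of Lorentzian (default) or Gaussian bands on top of a
fluorescence-like cubic polynomial baseline, with per-pixel multiplicative
amplitude jitter, additive Gaussian noise, and optional cosmic-ray spikes.
Everything is driven by explicit seeds and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import HyperspectralMap, Spectrum, WavenumberAxis, validate_mask

__all__ = [
    "BandSpec",
    "ClassSignature",
    "TissueLayoutConfig",
    "NoiseConfig",
    "PlacementError",
    "default_signatures",
    "avac_hypermethylated_signature",
    "render_signature",
    "generate_layout",
    "generate_map",
    "simulate_labeled_spectra",
]

TUMOR_CLASSES = {"AVAC": (1, 2), "cPDAC": (3, 4), "IPMC": (5, 6)}


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: an analytic line shape on the wavenumber axis."""

    center: float  # cm^-1
    width: float  # full width at half maximum, cm^-1
    amplitude: float  # peak height, relative units
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if not (600.0 <= self.center <= 1900.0):
            raise ValueError("band center must lie within [600, 1900] cm^-1")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown line shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "lorentzian":
            g = self.width / 2.0
            return self.amplitude * g * g / (d * d + g * g)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * d * d / (self.width**2))


@dataclass(frozen=True)
class ClassSignature:
    """The noiseless chemistry of one tissue class.

    ``baseline_coeffs`` are polynomial coefficients (constant first, order
    <= 3) in the normalized coordinate t = (wavenumber - 600) / 1300, giving
    a smooth fluorescence-like background.
    """

    class_index: int
    bands: tuple[BandSpec, ...]
    baseline_coeffs: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if not (0 <= self.class_index <= 6):
            raise ValueError("class_index must be in 0..6")
        if len(self.baseline_coeffs) > 4:
            raise ValueError("baseline polynomial order must be <= 3")
        if self.class_index != 0 and not self.bands:
            raise ValueError("classes 1-6 need at least one band")

    @property
    def max_amplitude(self) -> float:
        return max((b.amplitude for b in self.bands), default=0.0)

    def scaled(self, factor: float) -> "ClassSignature":
        """Return a copy with every band amplitude multiplied by ``factor``."""
        return replace(
            self,
            bands=tuple(replace(b, amplitude=b.amplitude * factor) for b in self.bands),
        )


def _L(center: float, width: float, amplitude: float) -> BandSpec:
    return BandSpec(center, width, amplitude, "lorentzian")


def default_signatures() -> list[ClassSignature]:
    """The reference seven-class signature library.

    Relative amplitudes are chosen so that on noiseless spectra the
    diagnostic band ratios order the nuclei as reported: beta-sheet ratio
    highest in cPDAC and lowest in AVAC, random-coil ratio highest in IPMC,
    methylation ratio highest in AVAC.
    """
    common_nucleus = [
        _L(785, 14, 0.35),  # DNA O-P-O breathing
        _L(1004, 8, 0.60),  # Phe ring breathing
        _L(1095, 18, 0.45),  # nu_s(PO2-) DNA backbone
        _L(1260, 40, 0.35),  # amide III envelope
        _L(1454, 18, 0.50),  # CH2/CH3 bending
    ]
    signatures = [
        # 0 stroma/empty: weak broad background only
        ClassSignature(
            0,
            bands=(
                _L(1004, 10, 0.04),
                BandSpec(1450, 60, 0.05, "gaussian"),
                BandSpec(1660, 70, 0.06, "gaussian"),
            ),
            baseline_coeffs=(0.60, -0.40, 0.10, 0.05),
        ),
        # 1 AVAC nucleus: methylation-marked DNA, amide I shifted high
        # (least beta-sheet), high overall protein
        ClassSignature(
            1,
            bands=tuple(
                common_nucleus
                + [
                    _L(879, 14, 0.30),  # DNA backbone
                    _L(1070, 16, 0.25),  # DNA backbone
                    _L(1128, 14, 0.20),
                    _L(1280, 18, 0.25),  # CH2 twist (methyl motions)
                    _L(1391, 16, 0.55),  # delta(CH2, CH3) methylation marker
                    _L(1489, 16, 0.25),
                    _L(1223, 10, 0.08),  # beta amide III, weakest of nuclei
                    _L(1670, 26, 0.85),  # amide I, high-wavenumber (turns/other)
                ]
            ),
            baseline_coeffs=(0.90, -0.55, 0.15, 0.05),
        ),
        # 2 AVAC cytoplasm: methylated proteins + reduced cytochrome C
        ClassSignature(
            2,
            bands=(
                _L(1004, 8, 0.50),
                _L(1128, 14, 0.35),  # reduced cytochrome C marker
                _L(1260, 40, 0.30),
                _L(1299, 16, 0.40),
                _L(1378, 16, 0.30),
                _L(1448, 18, 0.60),
                _L(1585, 16, 0.15),  # cytochrome C companion
                _L(1657, 30, 0.65),  # amide I, mostly alpha/other
            ),
            baseline_coeffs=(0.80, -0.45, 0.10, 0.05),
        ),
        # 3 cPDAC nucleus: beta-sheet-rich amide I at 1628 + strong beta amide III
        ClassSignature(
            3,
            bands=tuple(
                common_nucleus
                + [
                    _L(1391, 16, 0.18),
                    _L(1223, 10, 0.55),  # beta-sheet amide III
                    _L(1628, 24, 1.00),  # beta-sheet amide I
                    _L(1680, 20, 0.20),  # antiparallel beta shoulder
                ]
            ),
            baseline_coeffs=(0.70, -0.40, 0.10, 0.05),
        ),
        # 4 cPDAC cytoplasm: Phe/Trp-rich proteins (1208)
        ClassSignature(
            4,
            bands=(
                _L(1004, 8, 0.60),
                _L(1033, 10, 0.20),  # Phe companion
                _L(1208, 14, 0.55),  # C-C6H5 stretch, Phe/Trp
                _L(1245, 30, 0.30),
                _L(1450, 18, 0.45),
                _L(1660, 28, 0.75),
            ),
            baseline_coeffs=(0.75, -0.45, 0.12, 0.05),
        ),
        # 5 IPMC nucleus: random-coil-rich amide I at 1650, high protein
        ClassSignature(
            5,
            bands=tuple(
                common_nucleus
                + [
                    _L(1391, 16, 0.20),
                    _L(1223, 10, 0.22),  # intermediate beta content
                    _L(1650, 24, 1.05),  # random-coil amide I
                ]
            ),
            baseline_coeffs=(0.85, -0.50, 0.12, 0.05),
        ),
        # 6 IPMC cytoplasm: Tyr-rich, amide II, coil amide I at 1662
        ClassSignature(
            6,
            bands=(
                _L(1004, 8, 0.65),
                _L(1128, 14, 0.30),  # reduced cytochrome C
                _L(1170, 12, 0.45),  # Tyr C-H bending
                _L(1260, 40, 0.35),
                _L(1299, 16, 0.35),
                _L(1378, 16, 0.28),
                _L(1448, 18, 0.60),
                _L(1540, 18, 0.45),  # amide II
                _L(1662, 28, 0.85),  # turns/coil amide I
            ),
            baseline_coeffs=(0.85, -0.50, 0.12, 0.05),
        ),
    ]
    return signatures


def avac_hypermethylated_signature(base: ClassSignature | None = None) -> ClassSignature:
    """The high-methylation AVAC-nucleus variant (local hypermethylation).

    Methylation-marker and DNA-backbone band amplitudes are boosted relative
    to the base AVAC-nucleus signature.
    """
    if base is None:
        base = default_signatures()[1]
    boosted = {879: 1.5, 1070: 1.5, 1128: 1.6, 1280: 1.6, 1391: 1.7, 1489: 1.8}
    bands = tuple(
        replace(b, amplitude=b.amplitude * boosted.get(b.center, 1.0)) for b in base.bands
    )
    return replace(base, bands=bands)


def render_signature(sig: ClassSignature, axis: WavenumberAxis) -> Spectrum:
    """Evaluate a signature on an axis: sum of band profiles plus baseline."""
    wn = axis.values
    intensity = np.zeros_like(wn)
    for band in sig.bands:
        intensity += band.profile(wn)
    if any(c != 0.0 for c in sig.baseline_coeffs):
        t = (wn - 600.0) / 1300.0
        intensity += np.polynomial.polynomial.polyval(t, np.asarray(sig.baseline_coeffs))
    return Spectrum(axis, intensity)


def _render_bands_only(sig: ClassSignature, axis: WavenumberAxis) -> np.ndarray:
    wn = axis.values
    intensity = np.zeros_like(wn)
    for band in sig.bands:
        intensity += band.profile(wn)
    return intensity


@dataclass(frozen=True)
class TissueLayoutConfig:
    """Spatial stand-in for tissue morphology: round cells on stroma."""

    height: int = 80
    width: int = 80
    n_cells: int = 8
    nucleus_radius_px: int = 3
    cell_radius_px: int = 7
    tumor_type: str = "AVAC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_type not in TUMOR_CLASSES:
            raise ValueError(f"tumor_type must be one of {sorted(TUMOR_CLASSES)}")
        if not (0 < self.nucleus_radius_px < self.cell_radius_px):
            raise ValueError("require 0 < nucleus_radius_px < cell_radius_px")
        if 2 * self.cell_radius_px + 1 > min(self.height, self.width):
            raise ValueError("cell_radius_px does not fit within the map")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model for generated maps.

    ``sigma_rel`` scales additive Gaussian noise as a fraction of the class
    signature's maximum band amplitude; ``cosmic_rate`` is the expected
    number of cosmic-ray spikes per 1000 spectra.
    """

    sigma_rel: float = 0.02
    cosmic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be non-negative")
        if self.cosmic_rate < 0:
            raise ValueError("cosmic_rate must be non-negative")


def generate_layout(cfg: TissueLayoutConfig) -> np.ndarray:
    """Place non-overlapping disk cells (cytoplasm with a nucleus core) on stroma.

    Returns a (height, width) label mask; deterministic for a given seed.
    """
    nucleus_class, cytoplasm_class = TUMOR_CLASSES[cfg.tumor_type]
    rng = np.random.default_rng(cfg.seed)
    mask = np.zeros((cfg.height, cfg.width), dtype=np.int64)
    r = cfg.cell_radius_px
    # Sequential rejection sampling can dead-end on tight packings, so the
    # whole placement restarts from scratch when an attempt budget runs out.
    centers: list[tuple[int, int]] = []
    max_attempts = 200 * max(cfg.n_cells, 1)
    for _restart in range(60):
        centers = []
        attempts = 0
        while len(centers) < cfg.n_cells and attempts < max_attempts:
            attempts += 1
            cy = int(rng.integers(r, cfg.height - r))
            cx = int(rng.integers(r, cfg.width - r))
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r) ** 2 for y, x in centers):
                centers.append((cy, cx))
        if len(centers) == cfg.n_cells:
            break
    else:
        raise PlacementError(
            f"could not place {cfg.n_cells} cells of radius {r} on a "
            f"{cfg.height}x{cfg.width} grid after 60 restarts"
        )
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask[d2 <= r * r] = cytoplasm_class
        mask[d2 <= cfg.nucleus_radius_px**2] = nucleus_class
    return mask


def generate_map(
    mask: np.ndarray,
    signatures: list[ClassSignature] | dict[int, ClassSignature],
    noise: NoiseConfig,
    axis: WavenumberAxis,
    *,
    jitter_sigma: float = 0.1,
    avac_hyper_fraction: float = 0.5,
    step_um: float = 1.0,
) -> HyperspectralMap:
    """Render a labeled mask into a noisy hyperspectral map.

    Each pixel is its class signature scaled by a lognormal amplitude jitter
    (sigma ``jitter_sigma`` in log space, applied to bands but not to the
    baseline), plus Gaussian noise of standard deviation
    ``noise.sigma_rel * max band amplitude`` and Poisson-placed cosmic
    spikes.  A fraction ``avac_hyper_fraction`` of AVAC-nucleus pixels is
    drawn from the hypermethylated signature variant, emulating locally
    elevated methylation.  Bit-reproducible for a given ``noise.seed``.
    """
    mask = validate_mask(np.asarray(mask))
    sig_by_class = (
        dict(signatures)
        if isinstance(signatures, dict)
        else {s.class_index: s for s in signatures}
    )
    present = [int(c) for c in np.unique(mask) if c >= 0]
    missing = [c for c in present if c not in sig_by_class]
    if missing:
        raise ValueError(f"no signature for class(es) {missing}")

    rng = np.random.default_rng(noise.seed)
    h, w = mask.shape
    p = len(axis)
    cube = np.zeros((h, w, p), dtype=float)

    rendered: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for c in present:
        sig = sig_by_class[c]
        bands = _render_bands_only(sig, axis)
        baseline = render_signature(sig, axis).intensity - bands
        rendered[c] = (bands, baseline, sig.max_amplitude)
    hyper_bands = None
    if 1 in present and avac_hyper_fraction > 0:
        hyper = avac_hypermethylated_signature(sig_by_class[1])
        hyper_bands = _render_bands_only(hyper, axis)

    flat_mask = mask.ravel()
    flat_cube = cube.reshape(-1, p)
    # Draws are ordered per pixel so that the cube is reproducible regardless
    # of class layout.
    jitter = np.exp(rng.normal(0.0, jitter_sigma, size=flat_mask.size)) if jitter_sigma > 0 else np.ones(flat_mask.size)
    hyper_draw = rng.random(flat_mask.size)
    for i, c in enumerate(flat_mask):
        if c < 0:
            c = 0  # unannotated pixels still need a spectrum: render as stroma
            if 0 not in rendered:
                continue
        bands, baseline, _ = rendered[int(c)]
        if int(c) == 1 and hyper_bands is not None and hyper_draw[i] < avac_hyper_fraction:
            bands = hyper_bands
        flat_cube[i] = bands * jitter[i] + baseline
    if noise.sigma_rel > 0:
        sigma_px = np.array(
            [rendered[int(c) if c >= 0 else 0][2] * noise.sigma_rel for c in flat_mask]
        )
        flat_cube += rng.normal(0.0, 1.0, size=flat_cube.shape) * sigma_px[:, None]
    if noise.cosmic_rate > 0:
        n_spikes = rng.poisson(noise.cosmic_rate / 1000.0, size=flat_mask.size)
        for i in np.nonzero(n_spikes)[0]:
            pos = rng.integers(0, p, size=n_spikes[i])
            amp = rng.uniform(5.0, 20.0, size=n_spikes[i])
            scale = rendered[int(flat_mask[i]) if flat_mask[i] >= 0 else 0][2]
            flat_cube[i, pos] += amp * scale
    return HyperspectralMap(axis=axis, cube=cube, step_um=step_um, mask=mask)


def simulate_labeled_spectra(
    n_per_class: int,
    signatures: list[ClassSignature] | None = None,
    noise: NoiseConfig = NoiseConfig(),
    axis: WavenumberAxis | None = None,
    *,
    jitter_sigma: float = 0.1,
    avac_hyper_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a balanced labeled training set directly (no spatial layout).

    Returns ``(X, y)`` with ``X`` of shape (7 * n_per_class, len(axis)) and
    integer labels ``y``.  Equivalent to sampling pixels of each class from
    generated maps; used to build classifier benchmarks quickly.
    """
    from .core import acquisition_axis

    if signatures is None:
        signatures = default_signatures()
    if axis is None:
        axis = acquisition_axis()
    classes = sorted(s.class_index for s in signatures)
    mask = np.repeat(np.asarray(classes, dtype=np.int64), n_per_class)[None, :]
    hmap = generate_map(
        mask,
        signatures,
        noise,
        axis,
        jitter_sigma=jitter_sigma,
        avac_hyper_fraction=avac_hyper_fraction,
    )
    return hmap.spectra(), mask.ravel().copy()
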