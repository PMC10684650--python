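"""Spectra conditioning: baseline correction, smoothing, trimming, augmentation.

The chain order is fixed — polynomial baseline correction, Savitzky-Golay
smoothing, then trimming/resampling onto the canonical 320-point grid over
[650, 1800] cm^-1.  Baseline correction uses iterative polynomial fitting
(fit, clip the working spectrum to the fit, refit) so that Raman peaks do
not drag the baseline upward; a plain least-squares fit is available via
``method="ols"``.

Training-set augmentation adds zero-mean Gaussian noise replicates; with
the default ``n_copies=2`` the training set triples in size.

``pack_int64``/``unpack_int64`` encode a (Raman shift, intensity) pair into
one 64-bit integer (shift quantized to 0.01 cm^-1 in the high 32 bits,
intensity quantized to 0.001 in the low 32 bits).  The default pipeline
aligns shifts by resampling onto the canonical grid instead, so the packed
encoding is provided but not used by any stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .core import CANONICAL_LEN, TRIM_HI, TRIM_LO, Spectrum, WavenumberAxis, canonical_axis

__all__ = [
    "PreprocessConfig",
    "RamanPreprocessor",
    "baseline_correct",
    "savgol_smooth",
    "trim_and_resample",
    "augment",
    "pack_int64",
    "unpack_int64",
]

SHIFT_STEP = 0.01  # cm^-1 per quantization unit (high 32 bits)
INTENSITY_STEP = 0.001  # intensity units per quantization unit (low 32 bits)
_U32_MAX = 2**32 - 1


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain (reference protocol defaults)."""

    baseline_order: int = 3
    sg_order: int = 3
    sg_window: int = 15
    trim_lo: float = TRIM_LO
    trim_hi: float = TRIM_HI
    target_len: int = CANONICAL_LEN
    baseline_method: str = "iterative"
    sg_mode: str = "interp"

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_order:
            raise ValueError("sg_window must exceed sg_order")
        if self.trim_lo >= self.trim_hi:
            raise ValueError("trim_lo must be < trim_hi")
        if self.target_len < self.sg_window:
            raise ValueError("target_len must be >= sg_window")
        if self.baseline_method not in ("iterative", "ols"):
            raise ValueError("baseline_method must be 'iterative' or 'ols'")
        if self.sg_mode not in ("interp", "mirror"):
            raise ValueError("sg_mode must be 'interp' or 'mirror'")


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra contain non-finite values")
    return X


def _baseline_matrix(
    Y: np.ndarray,
    wavenumbers: np.ndarray,
    order: int,
    method: str = "iterative",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fitted baselines for each row of Y (vectorized across spectra)."""
    t = (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0] + 1e-300)
    V = np.polynomial.polynomial.polyvander(t, order)  # (p, order+1)
    pinv = np.linalg.pinv(V)  # (order+1, p)
    work = Y.copy()
    fit = (V @ (pinv @ work.T)).T
    if method == "ols":
        return fit
    scale = np.maximum(np.max(np.abs(Y), axis=1, keepdims=True), 1e-300)
    for _ in range(max_iter):
        clipped = np.minimum(work, fit)
        new_fit = (V @ (pinv @ clipped.T)).T
        delta = np.max(np.abs(new_fit - fit) / scale)
        work, fit = clipped, new_fit
        if delta < tol:
            break
    return fit


def baseline_correct(s: Spectrum, order: int = 3, method: str = "iterative") -> Spectrum:
    """Subtract an iteratively fitted polynomial baseline of the given order."""
    if len(s) <= order + 1:
        raise ValueError("spectrum too short for the requested baseline order")
    y = _validate_matrix(s.intensity)
    baseline = _baseline_matrix(y, s.axis.values, order, method)
    return Spectrum(s.axis, (y - baseline)[0])


def savgol_smooth(s: Spectrum, order: int = 3, window: int = 15, mode: str = "interp") -> Spectrum:
    """Savitzky-Golay smoothing.

    The default edge mode fits the edge windows with a polynomial
    (scipy's ``interp``), which keeps polynomials up to the fit order
    exactly invariant; ``mode="mirror"`` reflect-pads instead.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if len(s) < window:
        raise ValueError("spectrum shorter than the smoothing window")
    y = _validate_matrix(s.intensity)
    return Spectrum(s.axis, savgol_filter(y, window, order, axis=1, mode=mode)[0])


def trim_and_resample(
    s: Spectrum,
    lo: float = TRIM_LO,
    hi: float = TRIM_HI,
    target_len: int = CANONICAL_LEN,
) -> Spectrum:
    """Linearly interpolate onto the uniform target grid over [lo, hi]."""
    wn = s.axis.values
    if wn[0] > lo or wn[-1] < hi:
        raise ValueError(
            f"axis [{wn[0]}, {wn[-1]}] does not cover the window [{lo}, {hi}]"
        )
    out_axis = canonical_axis(lo, hi, target_len)
    y = np.interp(out_axis.values, wn, s.intensity)
    return Spectrum(out_axis, y)


def augment(
    spectra: np.ndarray | list,
    sigma_rel: float = 0.02,
    n_copies: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Originals plus ``n_copies`` Gaussian-noise replicates per spectrum.

    The noise standard deviation for each spectrum is ``sigma_rel`` times
    that spectrum's maximum absolute intensity.  Output row count is
    ``(1 + n_copies) * n`` with originals first.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    if n_copies < 0:
        raise ValueError("n_copies must be non-negative")
    X = _validate_matrix(np.asarray(spectra, dtype=float))
    if n_copies == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    sigma = sigma_rel * np.max(np.abs(X), axis=1, keepdims=True)
    copies = [X]
    for _ in range(n_copies):
        copies.append(X + rng.normal(0.0, 1.0, size=X.shape) * sigma)
    return np.vstack(copies)


def pack_int64(shift_cm1: float, intensity: float) -> int:
    """Pack (shift, intensity) into one int64.

    High 32 bits: shift quantized to 0.01 cm^-1 (valid range [0, 4000]).
    Low 32 bits: intensity quantized to 0.001 (valid range
    [0, ~4.29e6]).  Strictly increasing in shift for fixed intensity.
    """
    if not (0.0 <= shift_cm1 <= 4000.0):
        raise ValueError("shift must lie within [0, 4000] cm^-1")
    q_shift = int(round(shift_cm1 / SHIFT_STEP))
    q_int = int(round(intensity / INTENSITY_STEP))
    if not (0 <= q_int <= _U32_MAX):
        raise ValueError(
            f"intensity {intensity} outside the quantizable range "
            f"[0, {_U32_MAX * INTENSITY_STEP}]"
        )
    return (q_shift << 32) | q_int


def unpack_int64(packed: int) -> tuple[float, float]:
    """Inverse of :func:`pack_int64` (to quantization precision)."""
    if packed < 0:
        raise ValueError("packed value must be non-negative")
    q_shift = packed >> 32
    q_int = packed & _U32_MAX
    return q_shift * SHIFT_STEP, q_int * INTENSITY_STEP


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer running the full conditioning chain.

    Rows of ``X`` are raw spectra on the acquisition axis given at
    construction; ``transform`` returns rows on the canonical
    ``target_len``-point grid over [trim_lo, trim_hi].  The chain is
    deterministic; use :func:`augment` separately for training-set noise
    replication.

    Parameters mirror :class:`PreprocessConfig`.
    """

    def __init__(
        self,
        axis: WavenumberAxis | None = None,
        baseline_order: int = 3,
        sg_order: int = 3,
        sg_window: int = 15,
        trim_lo: float = TRIM_LO,
        trim_hi: float = TRIM_HI,
        target_len: int = CANONICAL_LEN,
        baseline_method: str = "iterative",
        sg_mode: str = "interp",
    ) -> None:
        self.axis = axis
        self.baseline_order = baseline_order
        self.sg_order = sg_order
        self.sg_window = sg_window
        self.trim_lo = trim_lo
        self.trim_hi = trim_hi
        self.target_len = target_len
        self.baseline_method = baseline_method
        self.sg_mode = sg_mode

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            baseline_order=self.baseline_order,
            sg_order=self.sg_order,
            sg_window=self.sg_window,
            trim_lo=self.trim_lo,
            trim_hi=self.trim_hi,
            target_len=self.target_len,
            baseline_method=self.baseline_method,
            sg_mode=self.sg_mode,
        )

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "RamanPreprocessor":
        cfg = self._config()  # validates parameters
        X = _validate_matrix(X)
        if self.axis is None:
            raise ValueError("RamanPreprocessor requires the acquisition axis")
        if X.shape[1] != len(self.axis):
            raise ValueError(
                f"X has {X.shape[1]} spectral points but the axis has {len(self.axis)}"
            )
        self.n_features_in_ = X.shape[1]
        self.axis_out_ = canonical_axis(cfg.trim_lo, cfg.trim_hi, cfg.target_len)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "axis_out_"):
            self.fit(X)
        cfg = self._config()
        X = _validate_matrix(X)
        wn = self.axis.values
        baseline = _baseline_matrix(X, wn, cfg.baseline_order, cfg.baseline_method)
        Y = X - baseline
        Y = savgol_filter(Y, cfg.sg_window, cfg.sg_order, axis=1, mode=cfg.sg_mode)
        out_wn = self.axis_out_.values
        if wn[0] > cfg.trim_lo or wn[-1] < cfg.trim_hi:
            raise ValueError("acquisition axis does not cover the trim window")
        out = np.empty((Y.shape[0], cfg.target_len))
        for i in range(Y.shape[0]):
            out[i] = np.interp(out_wn, wn, Y[i])
        return out

    def transform_map(self, hmap) -> "HyperspectralMap":  # noqa: F821
        """Preprocess every pixel of a map, returning a canonical-grid map."""
        from .core import HyperspectralMap

        if self.axis is None:
            self.axis = hmap.axis
        elif self.axis != hmap.axis:
            raise ValueError("map axis differs from the preprocessor's axis")
        flat = self.fit(hmap.spectra()).transform(hmap.spectra())
        cube = flat.reshape(hmap.height, hmap.width, self.target_len)
        return HyperspectralMap(
            axis=self.axis_out_, cube=cube, step_um=hmap.step_um, mask=hmap.mask
        )
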