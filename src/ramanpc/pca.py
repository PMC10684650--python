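"""Per-class spectral extraction and PCA interpretation.

After classification, the spectra of selected classes (e.g. the three
nuclei classes) are pooled and decomposed by mean-centered PCA.  The
loadings' annotated extrema point at the wavenumbers driving the class
separation — e.g. a beta-sheet amide I band at 1628 cm^-1 versus a
random-coil band at 1650 cm^-1.

No unit-variance scaling is applied: band intensities share units and
scaling would distort the loading interpretation.  Loading signs are fixed
so each component's largest-magnitude element is positive, making scores
and plots reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .core import HyperspectralMap, WavenumberAxis
from .mapping import PredictionMap

__all__ = [
    "PCAResult",
    "LoadingPeak",
    "extract_class_spectra",
    "fit_pca",
    "score_centroids",
    "annotate_loadings",
]


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a class-spectra PCA."""

    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (k, p), rows orthonormal
    explained_variance_fraction: np.ndarray  # (k,)
    mean_spectrum: np.ndarray  # (p,)
    class_of_row: np.ndarray | None = None  # (n,)
    axis: WavenumberAxis | None = None

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    def reconstruct(self) -> np.ndarray:
        """mean + scores @ loadings."""
        return self.mean_spectrum + self.scores @ self.loadings


@dataclass(frozen=True)
class LoadingPeak:
    """A significant extremum of one loading vector."""

    component: int
    index: int
    wavenumber: float
    sign: str  # "maximum" | "minimum"
    magnitude: float


def extract_class_spectra(
    hmap: HyperspectralMap,
    pm: PredictionMap,
    class_set,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectra whose final class is in ``class_set``.

    Returns ``(spectra, classes, coords)`` where coords rows are (row, col)
    pixel positions.  An empty selection returns empty arrays (no error).
    """
    if pm.classes.shape != (hmap.height, hmap.width):
        raise ValueError("prediction map does not align with the hyperspectral map")
    class_set = set(int(c) for c in class_set)
    sel = np.isin(pm.classes, sorted(class_set))
    rows, cols = np.nonzero(sel)
    spectra = hmap.cube[rows, cols, :]
    classes = pm.classes[rows, cols]
    coords = np.column_stack([rows, cols])
    return spectra, classes, coords


def fit_pca(
    spectra: np.ndarray,
    k: int = 3,
    class_of_row: np.ndarray | None = None,
    axis: WavenumberAxis | None = None,
) -> PCAResult:
    """Mean-centered principal decomposition with a fixed sign convention."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must form a 2-D matrix")
    n, p = X.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k must lie in 1..min(n, p) = {min(n, p)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # sign fix: largest-magnitude element of each loading positive
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        mean_spectrum=pca.mean_.copy(),
        class_of_row=None if class_of_row is None else np.asarray(class_of_row),
        axis=axis,
    )


def score_centroids(
    res: PCAResult, n_bins: int = 50
) -> tuple[dict[int, np.ndarray], dict[int, list[np.ndarray]], list[np.ndarray]]:
    """Per-class score centroids and per-component count histograms.

    Histograms share bin edges across classes for each component, matching
    the "scores count" presentation.  Returns
    ``(centroids, histograms, bin_edges)`` with ``histograms[c][j]`` the
    counts of class ``c`` on component ``j``.
    """
    if res.class_of_row is None:
        classes = np.zeros(res.scores.shape[0], dtype=int)
    else:
        classes = np.asarray(res.class_of_row, dtype=int)
    present = np.unique(classes)
    centroids = {int(c): res.scores[classes == c].mean(axis=0) for c in present}
    bin_edges = [
        np.histogram_bin_edges(res.scores[:, j], bins=n_bins)
        for j in range(res.n_components)
    ]
    histograms = {
        int(c): [
            np.histogram(res.scores[classes == c, j], bins=bin_edges[j])[0]
            for j in range(res.n_components)
        ]
        for c in present
    }
    return centroids, histograms, bin_edges


def annotate_loadings(
    res: PCAResult, prominence: float | None = None
) -> list[LoadingPeak]:
    """Significant maxima and minima of each loading.

    ``prominence`` defaults to 5% of that loading's maximum absolute value.
    Peaks are local extrema found on the loading and on its negation.
    """
    if prominence is not None and prominence <= 0:
        raise ValueError("prominence must be positive")
    peaks: list[LoadingPeak] = []
    for comp in range(res.n_components):
        loading = res.loadings[comp]
        scale = float(np.max(np.abs(loading)))
        if scale == 0.0:
            continue
        prom = prominence if prominence is not None else 0.05 * scale
        for sign, vector in (("maximum", loading), ("minimum", -loading)):
            idx, _ = find_peaks(vector, prominence=prom)
            for i in idx:
                wavenumber = (
                    float(res.axis.values[i]) if res.axis is not None else float(i)
                )
                peaks.append(
                    LoadingPeak(
                        component=comp,
                        index=int(i),
                        wavenumber=wavenumber,
                        sign=sign,
                        magnitude=float(abs(loading[i])),
                    )
                )
    peaks.sort(key=lambda p: (p.component, p.index))
    return peaks
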