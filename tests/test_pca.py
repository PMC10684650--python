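import numpy as np
import pytest

import ramanpc as rp
from ramanpc.mapping import PredictionMap
from ramanpc.synth import _render_bands_only


def _eig_pca_oracle(X, k):
    """Covariance eigendecomposition: the independent small-matrix oracle."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    frac = w / w.sum()
    return frac[:k], V[:, :k].T


class TestFitPCA:
    def test_matches_eigendecomposition_oracle_on_6x5(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 5))
        res = rp.fit_pca(X, k=4)
        frac_oracle, loadings_oracle = _eig_pca_oracle(X, 4)
        np.testing.assert_allclose(
            res.explained_variance_fraction, frac_oracle, atol=1e-8
        )
        for i in range(4):
            dot = abs(np.dot(res.loadings[i], loadings_oracle[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_and_scores_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 12))
        res = rp.fit_pca(X, k=5)
        np.testing.assert_allclose(
            res.loadings @ res.loadings.T, np.eye(5), atol=1e-8
        )
        np.testing.assert_allclose(
            res.scores, (X - res.mean_spectrum) @ res.loadings.T, atol=1e-8
        )
        frac = res.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12) and frac.sum() <= 1 + 1e-12

    def test_rank_one_data_concentrates_variance(self):
        t = np.linspace(-1, 1, 9)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        X = 5.0 + t[:, None] * direction[None, :]
        res = rp.fit_pca(X, k=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 6))
        res = rp.fit_pca(X, k=6)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_at_data_rank(self):
        rng = np.random.default_rng(3)
        basis = rng.random((3, 20))
        X = rng.random((15, 3)) @ basis + 2.0
        res = rp.fit_pca(X, k=3)
        err = np.abs(res.reconstruct() - X).max() / np.abs(X).max()
        assert err < 1e-6

    def test_sign_convention_fixed(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 7))
        res = rp.fit_pca(X, k=3)
        for i in range(3):
            assert res.loadings[i, np.argmax(np.abs(res.loadings[i]))] > 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            rp.fit_pca(np.random.default_rng(0).random((4, 3)), k=5)


class TestExtractClassSpectra:
    @pytest.fixture()
    def map_with_predictions(self, small_map):
        pm = PredictionMap(classes=small_map.mask)
        return small_map, pm

    def test_all_classes_returns_every_pixel(self, map_with_predictions):
        hmap, pm = map_with_predictions
        spectra, classes, coords = rp.extract_class_spectra(hmap, pm, range(7))
        assert spectra.shape[0] == hmap.n_pixels

    def test_nuclei_selection_matches_generator_mask(self, map_with_predictions):
        hmap, pm = map_with_predictions
        spectra, classes, coords = rp.extract_class_spectra(hmap, pm, {1, 3, 5})
        expected = np.isin(hmap.mask, [1, 3, 5]).sum()
        assert spectra.shape[0] == expected
        assert set(np.unique(classes)) <= {1, 3, 5}

    def test_disjoint_sets_partition_the_map(self, map_with_predictions):
        hmap, pm = map_with_predictions
        n1 = rp.extract_class_spectra(hmap, pm, {0})[0].shape[0]
        n2 = rp.extract_class_spectra(hmap, pm, {1, 2})[0].shape[0]
        n3 = rp.extract_class_spectra(hmap, pm, {3, 4, 5, 6})[0].shape[0]
        assert n1 + n2 + n3 == hmap.n_pixels

    def test_empty_selection_returns_empty_not_error(self, map_with_predictions):
        hmap, pm = map_with_predictions
        spectra, classes, coords = rp.extract_class_spectra(hmap, pm, {6})
        assert spectra.shape[0] == 0


class TestScoreCentroids:
    def test_single_class_centroid_is_score_mean(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 8))
        res = rp.fit_pca(X, k=2, class_of_row=np.zeros(20, dtype=int))
        centroids, hists, edges = rp.score_centroids(res)
        np.testing.assert_allclose(centroids[0], res.scores.mean(axis=0), atol=1e-12)

    def test_symmetric_classes_have_opposite_pc1_centroids(self):
        rng = np.random.default_rng(6)
        direction = rng.random(10)
        offsets = np.concatenate([np.full(30, 3.0), np.full(30, -3.0)])
        X = offsets[:, None] * direction[None, :] + rng.normal(0, 0.05, (60, 10))
        classes = np.repeat([1, 3], 30)
        res = rp.fit_pca(X, k=2, class_of_row=classes)
        centroids, _, _ = rp.score_centroids(res)
        assert centroids[1][0] * centroids[3][0] < 0

    def test_histogram_counts_sum_to_class_sizes(self):
        rng = np.random.default_rng(7)
        X = rng.random((25, 6))
        classes = np.array([1] * 10 + [5] * 15)
        res = rp.fit_pca(X, k=2, class_of_row=classes)
        _, hists, _ = rp.score_centroids(res)
        assert hists[1][0].sum() == 10 and hists[5][1].sum() == 15


class TestAnnotateLoadings:
    def _result_with_loading(self, loading, axis):
        k, p = 1, loading.size
        return rp.PCAResult(
            scores=np.zeros((2, k)),
            loadings=loading[None, :] / np.linalg.norm(loading),
            explained_variance_fraction=np.array([1.0]),
            mean_spectrum=np.zeros(p),
            axis=axis,
        )

    def test_gaussian_bump_found_at_its_center(self, canonical):
        loading = rp.BandSpec(1628.0, 20.0, 1.0, "gaussian").profile(canonical.values)
        res = self._result_with_loading(loading, canonical)
        peaks = rp.annotate_loadings(res)
        maxima = [p for p in peaks if p.sign == "maximum"]
        assert len(maxima) == 1
        step = canonical.values[1] - canonical.values[0]
        assert abs(maxima[0].wavenumber - 1628.0) <= step

    def test_flat_loading_has_no_peaks(self, canonical):
        res = self._result_with_loading(np.ones(len(canonical)), canonical)
        assert rp.annotate_loadings(res) == []

    def test_negative_bump_reported_as_minimum(self, canonical):
        loading = -rp.BandSpec(1650.0, 20.0, 1.0, "gaussian").profile(canonical.values)
        loading += 1e-3  # keep the largest-|.|-element-positive convention moot
        res = self._result_with_loading(loading, canonical)
        peaks = rp.annotate_loadings(res)
        minima = [p for p in peaks if p.sign == "minimum"]
        assert any(abs(p.wavenumber - 1650.0) <= 4 for p in minima)


class TestBandRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_amide_band_difference_recovered_within_10_cm(self, seed, canonical):
        """Two nuclei classes differing in amide I position (1628 vs 1650):
        the separating component's extrema land within +-10 cm^-1 of both."""
        rng = np.random.default_rng(seed)
        n = 120
        spectra, classes = [], []
        for cls, center in ((3, 1628.0), (5, 1650.0)):
            band = rp.BandSpec(center, 24.0, 1.0).profile(canonical.values)
            base = rp.BandSpec(1004.0, 8.0, 0.6).profile(canonical.values)
            scale = np.exp(rng.normal(0, 0.1, size=n))
            noise = rng.normal(0, 0.02, size=(n, len(canonical)))
            spectra.append(scale[:, None] * (band + base)[None, :] + noise)
            classes.append(np.full(n, cls))
        X = np.vstack(spectra)
        classes = np.concatenate(classes)
        res = rp.fit_pca(X, k=3, class_of_row=classes, axis=canonical)
        centroids, _, _ = rp.score_centroids(res)
        sep = np.argmax(np.abs(centroids[3] - centroids[5]))
        peaks = [p for p in rp.annotate_loadings(res) if p.component == sep]
        assert any(abs(p.wavenumber - 1628.0) <= 10 for p in peaks)
        assert any(abs(p.wavenumber - 1650.0) <= 10 for p in peaks)
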