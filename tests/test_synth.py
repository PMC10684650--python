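import numpy as np
import pytest

import ramanpc as rp
from ramanpc.features import beta_sheet_ratio, methylation_ratio, random_coil_ratio
from ramanpc.synth import (
    PlacementError,
    _render_bands_only,
    avac_hypermethylated_signature,
)


class TestDefaultSignatures:
    def test_exactly_seven_with_valid_indices(self, signatures):
        assert [s.class_index for s in signatures] == list(range(7))
        for s in signatures[1:]:
            assert len(s.bands) >= 1

    def test_beta_sheet_ordering_of_nuclei(self, nuclei_spectra):
        """Beta-sheet ratio: highest in cPDAC nuclei, lowest in AVAC nuclei."""
        beta = {c: beta_sheet_ratio(s) for c, s in nuclei_spectra.items()}
        assert beta[3] > beta[5] > beta[1]

    def test_random_coil_highest_in_ipmc_nuclei(self, nuclei_spectra):
        coil = {c: random_coil_ratio(s) for c, s in nuclei_spectra.items()}
        assert coil[5] == max(coil.values())

    def test_methylation_highest_in_avac_nuclei(self, nuclei_spectra):
        meth = {c: methylation_ratio(s) for c, s in nuclei_spectra.items()}
        assert meth[1] == max(meth.values())
        # the hypermethylated variant is even more extreme
        axis = nuclei_spectra[1].axis
        hyper = rp.Spectrum(axis, _render_bands_only(avac_hypermethylated_signature(), axis))
        assert methylation_ratio(hyper) > meth[1]

    @pytest.mark.parametrize("scale", [0.3, 1.0, 4.5])
    def test_orderings_survive_amplitude_scaling(self, signatures, canonical, scale):
        spectra = {
            c: rp.Spectrum(
                canonical, _render_bands_only(signatures[c].scaled(scale), canonical)
            )
            for c in (1, 3, 5)
        }
        assert beta_sheet_ratio(spectra[3]) > beta_sheet_ratio(spectra[1])
        assert random_coil_ratio(spectra[5]) == max(
            random_coil_ratio(s) for s in spectra.values()
        )
        assert methylation_ratio(spectra[1]) == max(
            methylation_ratio(s) for s in spectra.values()
        )


class TestRenderSignature:
    def test_empty_signature_renders_zero(self, canonical):
        sig = rp.ClassSignature(0, bands=(), baseline_coeffs=(0.0,))
        assert np.all(rp.render_signature(sig, canonical).intensity == 0.0)

    def test_single_lorentzian_peaks_at_center(self, canonical):
        sig = rp.ClassSignature(1, bands=(rp.BandSpec(1004.0, 30.0, 2.5),))
        y = rp.render_signature(sig, canonical).intensity
        i = np.argmax(y)
        nearest = np.argmin(np.abs(canonical.values - 1004.0))
        assert i == nearest
        assert y[i] == pytest.approx(2.5, rel=0.02)

    def test_rendering_is_linear_in_amplitudes(self, signatures, canonical):
        sig = signatures[3]
        y1 = _render_bands_only(sig, canonical)
        y2 = _render_bands_only(sig.scaled(2.0), canonical)
        np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-12)


class TestGenerateLayout:
    def test_no_cells_gives_pure_stroma(self):
        cfg = rp.TissueLayoutConfig(height=20, width=20, n_cells=0, seed=1)
        assert np.all(rp.generate_layout(cfg) == 0)

    def test_deterministic_for_fixed_seed(self):
        cfg = rp.TissueLayoutConfig(height=40, width=40, n_cells=4, seed=9)
        np.testing.assert_array_equal(rp.generate_layout(cfg), rp.generate_layout(cfg))

    @pytest.mark.parametrize("tumor_type", ["AVAC", "cPDAC", "IPMC"])
    def test_nuclei_interior_to_their_cells(self, tumor_type):
        from ramanpc.synth import TUMOR_CLASSES

        cfg = rp.TissueLayoutConfig(
            height=50, width=50, n_cells=5, tumor_type=tumor_type, seed=2
        )
        mask = rp.generate_layout(cfg)
        nucleus, cytoplasm = TUMOR_CLASSES[tumor_type]
        assert set(np.unique(mask)) == {0, nucleus, cytoplasm}
        rows, cols = np.nonzero(mask == nucleus)
        for r, c in zip(rows, cols):
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                assert mask[rr, cc] in (nucleus, cytoplasm)

    def test_impossible_packing_raises(self):
        cfg = rp.TissueLayoutConfig(height=20, width=20, n_cells=50, seed=0)
        with pytest.raises(PlacementError):
            rp.generate_layout(cfg)


class TestGenerateMap:
    def test_noiseless_map_equals_rendered_signatures(self, signatures, canonical):
        mask = np.array([[0, 3], [5, 3]])
        hmap = rp.generate_map(
            mask, signatures, rp.NoiseConfig(sigma_rel=0.0, seed=0), canonical,
            jitter_sigma=0.0, avac_hyper_fraction=0.0,
        )
        for c in (0, 3, 5):
            expected = rp.render_signature(signatures[c], canonical).intensity
            for r, cc in zip(*np.nonzero(mask == c)):
                np.testing.assert_array_equal(hmap.cube[r, cc], expected)

    def test_seeded_cube_is_bit_reproducible(self, signatures, canonical):
        mask = np.array([[1, 2, 0], [4, 6, 5]])
        noise = rp.NoiseConfig(sigma_rel=0.05, cosmic_rate=5.0, seed=42)
        m1 = rp.generate_map(mask, signatures, noise, canonical)
        m2 = rp.generate_map(mask, signatures, noise, canonical)
        np.testing.assert_array_equal(m1.cube, m2.cube)

    def test_missing_signature_is_configuration_error(self, signatures, canonical):
        with pytest.raises(ValueError, match="no signature"):
            rp.generate_map(
                np.array([[6]]), signatures[:5], rp.NoiseConfig(seed=0), canonical
            )

    def test_noisy_replicate_mean_converges_to_signature(self, signatures, canonical):
        """Monte-Carlo: the mean over 1000 noisy draws of one pixel approaches
        the noiseless spectrum within 3 sigma / sqrt(1000) per point."""
        sigma_rel = 0.05
        n_rep = 1000
        mask = np.zeros((1, n_rep), dtype=int) + 3
        hmap = rp.generate_map(
            mask, signatures, rp.NoiseConfig(sigma_rel=sigma_rel, seed=5), canonical,
            jitter_sigma=0.0, avac_hyper_fraction=0.0,
        )
        clean = rp.render_signature(signatures[3], canonical).intensity
        sigma = sigma_rel * signatures[3].max_amplitude
        se = sigma / np.sqrt(n_rep)
        err = np.abs(hmap.cube[0].mean(axis=0) - clean)
        # per-point 3-sigma band holds for nearly all points; the sup over
        # 320 points stays within 5 standard errors
        assert np.mean(err < 3.0 * se) > 0.98
        assert err.max() < 5.0 * se

    def test_noiseless_ratios_separate_nuclei_with_zero_overlap(self, signatures, acq_axis):
        """Class-purity invariant: per-pixel ratios of a noiseless map keep the
        three nuclei classes disjoint even with amplitude jitter."""
        mask = np.repeat(np.array([[1, 3, 5]]), 60, axis=0).T.reshape(3, 60)
        hmap = rp.generate_map(
            mask, signatures, rp.NoiseConfig(sigma_rel=0.0, seed=8), acq_axis,
            jitter_sigma=0.1,
        )
        pre = rp.RamanPreprocessor(axis=acq_axis)
        X = pre.fit(hmap.spectra()).transform(hmap.spectra())
        R = rp.feature_matrix(X, pre.axis_out_, np.zeros(X.shape[0], dtype=int))
        meth, beta, coil = R[:, 2], R[:, 5], R[:, 7]
        labels = hmap.mask.ravel()
        # beta-sheet separates cPDAC above the others
        assert beta[labels == 3].min() > max(beta[labels == 1].max(), beta[labels == 5].max())
        # random-coil separates IPMC above the others
        assert coil[labels == 5].min() > max(coil[labels == 1].max(), coil[labels == 3].max())
        # methylation separates AVAC (both variants) above the others
        assert meth[labels == 1].min() > max(meth[labels == 3].max(), meth[labels == 5].max())


def test_simulate_labeled_spectra_balanced(self=None):
    X, y = rp.simulate_labeled_spectra(5, noise=rp.NoiseConfig(sigma_rel=0.0, seed=0))
    assert X.shape == (35, len(rp.acquisition_axis()))
    assert np.bincount(y).tolist() == [5] * 7
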