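import numpy as np
import pytest
from hypothesis import settings

import ramanpc as rp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def canonical():
    return rp.canonical_axis()


@pytest.fixture(scope="session")
def acq_axis():
    return rp.acquisition_axis()


@pytest.fixture(scope="session")
def signatures():
    return rp.default_signatures()


@pytest.fixture(scope="session")
def nuclei_spectra(signatures, canonical):
    """Noiseless band-only spectra of the three nuclei classes, keyed by class."""
    from ramanpc.synth import _render_bands_only

    return {
        c: rp.Spectrum(canonical, _render_bands_only(signatures[c], canonical))
        for c in (1, 3, 5)
    }


@pytest.fixture(scope="session")
def small_map(signatures, acq_axis):
    """A 12x12 noisy AVAC map with ground-truth mask."""
    mask = rp.generate_layout(
        rp.TissueLayoutConfig(
            height=12, width=12, n_cells=1, nucleus_radius_px=2,
            cell_radius_px=4, tumor_type="AVAC", seed=3,
        )
    )
    return rp.generate_map(
        mask, signatures, rp.NoiseConfig(sigma_rel=0.02, seed=3), acq_axis
    )
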