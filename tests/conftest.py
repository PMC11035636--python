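import numpy as np
import pytest

import halolipidome as hl
from halolipidome.simulate import INTERNAL_STANDARD_ID


@pytest.fixture(scope="session")
def noiseless_design():
    return hl.default_design(
        seed=7, abundance_sigma=0.0, mz_jitter_sd=0.0, spurious_peak_rate=0.0
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_design):
    """Zero-noise default study: (table, truth, spectra)."""
    table, truth = hl.simulate_lipidome(noiseless_design)
    spectra = hl.simulate_spectra(noiseless_design, truth)
    return table, truth, spectra


@pytest.fixture(scope="session")
def noiseless_merged(noiseless_study):
    """Recovery-corrected, adduct-merged zero-noise table plus truth."""
    table, truth, _ = noiseless_study
    corrected = hl.correct_recovery(table, INTERNAL_STANDARD_ID)
    merged, _ = hl.merge_adducts(corrected)
    return merged, truth


def random_spectrum(rng, n_peaks, feature_id="s", precursor=None):
    """A random but valid MS² spectrum for property tests."""
    precursor = float(precursor if precursor is not None else rng.uniform(400, 1200))
    mz = np.sort(rng.uniform(50, precursor - 5, size=n_peaks))
    intensity = rng.uniform(1, 100, size=n_peaks)
    return hl.MsSpectrum(
        feature_id=feature_id,
        precursor_mz=precursor,
        peaks=np.column_stack([mz, intensity]),
    )
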