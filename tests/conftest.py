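import numpy as np
import pytest

from opticmol import AbsorbanceSpectrum, EEM, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end tests: coarser emission grid,
    fewer formulae, fewer plants; study-structure otherwise intact."""
    cfg = GeneratorConfig(n_samples=20, em_step=8.0, n_formulae=400,
                          n_noise_peaks=30, plants_per_driver=6,
                          plant_drivers=("c1", "suva254", "fi"))
    return generate_cohort(cfg, seed=11)


@pytest.fixture()
def exp_spectrum():
    """Single-exponential decadic absorbance spectrum, S = 0.018 1/nm."""
    wl = np.arange(250.0, 801.0, 1.0)
    a = 0.5 * np.exp(-0.018 * (wl - 275.0))
    return AbsorbanceSpectrum(wl, a, path_length=0.01)


@pytest.fixture()
def flat_eem():
    """Unmasked EEM with constant intensity 2.0 on a small regular grid."""
    ex = np.arange(260.0, 460.0, 5.0)
    em = np.arange(250.0, 706.0, 2.0)
    inten = np.full((len(ex), len(em)), 2.0)
    return EEM(ex, em, inten, np.zeros_like(inten, dtype=bool))
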