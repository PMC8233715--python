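"""Shared fixtures: small grids and session-scoped synthetic datasets."""

import numpy as np
import pytest

import nirspec_fa as nf


@pytest.fixture
def small_grid():
    """A 21-point grid cheap enough for exact-arithmetic operator tests."""
    return nf.WavelengthGrid(start_nm=1000.0, step_nm=0.5, n_points=21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim300():
    """Synthetic study at the recoverability regime: n=300, gain SD 0.1,
    noise SD 0.005, fixed seed.  Returns (config, reference, averaged spectra)."""
    config = nf.SimulationConfig(n_samples=300, seed=1)
    reference = nf.simulate_concentrations(config)
    spectra = nf.simulate_spectra(reference, config, n_scans=2)
    return config, reference, nf.average_replicates(spectra)


@pytest.fixture(scope="session")
def suite332():
    """Full-scale synthetic study (n=332) with the 48 packaged models run."""
    config = nf.SimulationConfig(n_samples=332, seed=3)
    reference = nf.simulate_concentrations(config)
    spectra = nf.average_replicates(
        nf.simulate_spectra(reference, config, n_scans=2)
    )
    suite = nf.run_suite(spectra, reference, seed=3)
    return suite
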