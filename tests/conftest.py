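import pytest

import nitroquant as nq


@pytest.fixture(scope="session")
def registry():
    return nq.builtin_registry()


@pytest.fixture(scope="session")
def nf_model():
    """Signal model with every stochastic term switched off."""
    return nq.default_signal_model().noise_free()


@pytest.fixture(scope="session")
def default_model():
    return nq.default_signal_model()


@pytest.fixture(scope="session")
def nf_calibration(nf_model):
    """Noise-free calibration series (one spot per level suffices)."""
    spectra, design = nq.simulate_calibration_series(model=nf_model, n_spots=1, seed=101)
    return spectra, design


@pytest.fixture(scope="session")
def nf_simple_models(nf_calibration):
    spectra, design = nf_calibration
    return nq.fit_simple_models(spectra, design)


@pytest.fixture(scope="session")
def nf_interference_models(nf_model):
    spectra, design = nq.simulate_interference_series(model=nf_model, n_spots=1, seed=102)
    return nq.fit_interference_models(spectra, design)
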