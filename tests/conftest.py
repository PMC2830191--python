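import warnings

import pytest

from methylsieve.filter_pipeline import PipelineConfig, run_pipeline
from methylsieve.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # degenerate spectra and sparse benchmark classes warn by design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def default_run():
    """One seeded reference run of the full pipeline under default conditions."""
    config = SimulationConfig(seed=11, n_proteins=40)
    proteins, truth, spectra = simulate_dataset(config)
    result = run_pipeline(spectra, proteins, PipelineConfig())
    return config, proteins, truth, spectra, result


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free reference run: no mass error, no contaminants."""
    config = SimulationConfig(
        seed=13, n_proteins=40, mass_error_sigma=0.0, contaminant_rate=0.0
    )
    proteins, truth, spectra = simulate_dataset(config)
    result = run_pipeline(spectra, proteins, PipelineConfig())
    return config, proteins, truth, spectra, result
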