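import numpy as np
import pytest

from skintherm.pipeline import analyze_measurements, extract_from_simulation
from skintherm.simulate import GenerativeConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full-scale end-to-end simulated study (35 subjects, 1680 images).

    Session-scoped: simulated, registered, extracted and analyzed once, then
    shared by every test that inspects study-level estimates.
    """
    config = GenerativeConfig(n_subjects=35, rng_seed=7)
    sim = simulate_study(config)
    measurements = extract_from_simulation(sim)
    results = analyze_measurements(measurements)
    return {"config": config, "sim": sim,
            "measurements": measurements, "results": results}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
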