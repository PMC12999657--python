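import numpy as np
import pytest

import doxpbpk as d


@pytest.fixture(scope="session")
def fast_settings():
    """Looser solver tolerances for tests that run many simulations."""
    return d.SimulationSettings(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def default_scenario():
    """Bundled study setup: 75 mg tablet, reference subject, no genotype."""
    return d.ParentMetabolitePBPK.default()


@pytest.fixture(scope="session")
def default_result(default_scenario):
    return default_scenario.simulate()


@pytest.fixture(scope="session")
def fast_scenario(fast_settings):
    return d.ParentMetabolitePBPK.default(settings=fast_settings)


@pytest.fixture(scope="session")
def sampling_times():
    """12 sampling times spanning absorption through the terminal phase."""
    return np.array([1.0, 2, 3, 4, 6, 8, 12, 24, 36, 48, 72, 96])


@pytest.fixture(scope="session")
def clean_metabolite_profile(fast_scenario, sampling_times):
    """Noise-free metabolite concentrations at the sampling times."""
    grid = np.concatenate([[0.0], sampling_times])
    sim = fast_scenario.simulate(duration_h=96, output_grid_h=grid)
    met = sim.profile("metabolite")
    return d.ConcentrationTimeProfile(
        "nordoxepin", sampling_times, met.concentrations[1:]
    )
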