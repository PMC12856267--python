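import numpy as np
import pytest

from masld_cua.cohort import CohortSpec, generate_sf36_panel
from masld_cua.mapping import MappingCoefficients, build_utility_series


@pytest.fixture(scope="session")
def coeffs():
    return MappingCoefficients.default()


@pytest.fixture(scope="session")
def noise_free_series():
    """27 patients, exact 0.010125/month utility slope, no noise."""
    spec = CohortSpec(random_intercept_sd=0.0, residual_sd=0.0, seed=11)
    return build_utility_series(generate_sf36_panel(spec))


@pytest.fixture(scope="session")
def noisy_series():
    """Default study conditions: random intercepts and residual noise."""
    spec = CohortSpec(seed=7)
    return build_utility_series(generate_sf36_panel(spec))
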