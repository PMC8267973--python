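import numpy as np
import pytest

from imtlogistic import REFERENCE_CURVES, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def curves():
    """The four reference cohort curves keyed by group label."""
    return REFERENCE_CURVES


@pytest.fixture(scope="session")
def noise_free_aggregate():
    """62 exact observations on the aggregate-group curve (31 bilateral patients)."""
    spec = CohortSpec(
        group="aggregate",
        n_patients=31,
        age_range=(19.0, 74.0),
        true_params=REFERENCE_CURVES["aggregate"],
        noise_sd=0.0,
        bilateral=True,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
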