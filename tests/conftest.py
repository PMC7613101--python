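import numpy as np
import pytest

import tractnorm as tn


@pytest.fixture(scope="session")
def small_cohort():
    """30 controls + 4 patients, one metric, no injected anomalies."""
    spec = tn.CohortSpec(n_controls=30, n_patients=4, seed=101)
    return tn.generate_cohort(spec)


@pytest.fixture(scope="session")
def lesion_cohort():
    """21 controls + 3 patients with a 5-sigma bump on AF_left sections 8-12."""
    spec = tn.CohortSpec(
        n_controls=21, n_patients=3, seed=5,
        anomalies=(tn.AnomalySpec("AF", "left", "RISH0", 8, 5, 5.0),),
    )
    return tn.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
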