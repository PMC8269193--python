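import numpy as np
import pytest

from epwscreen.outcomes import load_reference, outcome_frame
from epwscreen.standards import epw_table, load_default_standards
from epwscreen.synthetic_cohort import CohortConfig, generate_frame


@pytest.fixture(scope="session")
def registry():
    return load_default_standards()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def cohort(registry, reference):
    """One mid-sized tuned cohort with EPW and outcome tables attached."""
    frame = generate_frame(CohortConfig(n_records=4000, seed=20240101))
    epw = epw_table(frame, registry)
    outcomes = outcome_frame(frame, reference)
    return frame, epw, outcomes


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
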