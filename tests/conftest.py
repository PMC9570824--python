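import numpy as np
import pytest
from hypothesis import settings

from radarsleep.synthetic_data import CohortSpec, generate_recording

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_recording():
    """One 10-min recording with a handful of events, shared read-only."""
    spec = CohortSpec(
        n_participants=1, duration_s=600.0, ahi_range=(40.0, 40.0), seed=11
    )
    return generate_recording(spec, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
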