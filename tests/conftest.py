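import numpy as np
import pytest

from vmdoc.preprocess import preprocess_recording
from vmdoc.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Nine short preprocessed recordings (3 per class) for fast unit tests."""
    spec = CohortSpec(n_per_class=3, duration_s=4.0, seed=11)
    return [preprocess_recording(r) for r in generate_cohort(spec)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def protocol_result():
    """Full protocol on the default synthetic cohort (15/class, 60 s, seed 0)."""
    from vmdoc.experiments import run_protocol
    return run_protocol(seed=0)
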