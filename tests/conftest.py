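import numpy as np
import pytest

from earpiece import derive, dosimetry, synth


@pytest.fixture(scope="session")
def curve():
    return dosimetry.default_calibration()


@pytest.fixture(scope="session")
def cohort():
    """Default-configuration synthetic cohort, shared across tests."""
    return synth.generate_cohort(synth.GeneratorConfig(n=2000), seed=424242)


@pytest.fixture(scope="session")
def derived(cohort, curve):
    return derive.attach_derived(cohort.participants, cohort.segments, curve, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
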