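import numpy as np
import pytest

from gdctac import DecayConfig, clinical_frames, expected_counts, generate_fixture_params


@pytest.fixture(scope="session")
def cases():
    """The nine bundled clinical GDC parameter sets, keyed by case id."""
    return {c.case_id: c for c in generate_fixture_params()}


@pytest.fixture(scope="session")
def case_list():
    return generate_fixture_params()


@pytest.fixture(scope="session")
def frames():
    return clinical_frames()


@pytest.fixture(scope="session")
def no_decay():
    return DecayConfig(enabled=False)


@pytest.fixture(scope="session")
def noiseless_tacs(case_list, frames, no_decay):
    """Noiseless expected-count TACs for every clinical case."""
    return {
        c.case_id: frames.with_counts(expected_counts(c.params, frames, no_decay))
        for c in case_list
    }


#: MRT values (min) as printed for the nine clinical cases: (fast, washout)
PRINTED_MRTS = {
    "1L": (0.931, 463.9),
    "1R": (0.716, 212.2),
    "1T": (0.792, 278.3),
    "2L": (0.798, 211.6),
    "2R": (1.073, 699.0),
    "2T": (0.937, 339.3),
    "3L": (0.677, 439.5),
    "3R": (0.682, 312.4),
    "3T": (0.657, 350.3),
}


@pytest.fixture(scope="session")
def printed_mrts():
    return PRINTED_MRTS
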