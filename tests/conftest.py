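import itertools

import pytest

from pmjq import reference
from pmjq.model import CheckpointMap, PatientRecord, Technique, maps_from_flags


def all_side_maps():
    """All 2^5 = 32 checkpoint maps."""
    return [CheckpointMap.from_flags(bits) for bits in itertools.product((0, 1), repeat=5)]


def all_bilateral_patients(technique=Technique.DIRECTED):
    """All 2^10 = 1024 bilateral flag combinations as patients."""
    out = []
    for i, bits in enumerate(itertools.product((0, 1), repeat=10)):
        right, left = maps_from_flags(bits)
        out.append(PatientRecord(f"P{i:04d}", technique, right=right, left=left))
    return out


@pytest.fixture(scope="session")
def side_maps():
    return all_side_maps()


@pytest.fixture(scope="session")
def bilateral_patients():
    return all_bilateral_patients()


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic reconstruction of the published two-group cohort."""
    return reference.reconstructed_study_cohort()
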