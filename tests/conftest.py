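import numpy as np
import pytest

from medocular.config import StudyConfig, IcaParams
from medocular.montage import make_montage
from medocular.synth import SegmentSpec, SubjectSpec, generate_cohort, simulate_session


@pytest.fixture(scope="session")
def montage31():
    return make_montage(31)


@pytest.fixture(scope="session")
def montage8():
    """Small montage that still carries the ocular anchor electrodes."""
    return make_montage(8, labels=["Fp1", "Fp2", "F7", "F8", "Cz", "Pz", "O1", "O2"])


@pytest.fixture(scope="session")
def subject():
    return SubjectSpec(id="T001", weekly_practice_min=100.0,
                       years_since_course=2.0, ocular_scale=0.9, seed=77)


@pytest.fixture(scope="session")
def short_segment():
    return SegmentSpec(task="IMW", condition="CPL", duration_s=120.0)


@pytest.fixture(scope="session")
def session_with_truth(subject, short_segment, montage31):
    """One simulated 120-s task segment on the full cap, with ground truth."""
    return simulate_session(subject, short_segment, montage31)


@pytest.fixture(scope="session")
def fast_config():
    """Small-montage, short-duration configuration for end-to-end tests."""
    cfg = StudyConfig(n_subjects=4, duration_s=60.0, n_eeg=8, seed=11)
    cfg.ica = IcaParams(rank=8, max_iter=100)
    return cfg


@pytest.fixture(scope="session")
def cohort24():
    return generate_cohort(24, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
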