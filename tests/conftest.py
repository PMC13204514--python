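import numpy as np
import pytest

from strokefuse.cohort import CohortConfig, SyntheticCohort
from strokefuse.pipeline import extract_subject


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def tiny_config(**overrides) -> CohortConfig:
    """A fast-to-generate cohort configuration for unit tests."""
    base = dict(n_subjects=3, n_chronic_completers=2, n_runs_per_visit=2,
                n_frames=32, grid_shape=(12, 12, 12),
                lesion_volume_range=(8, 25), seed=99)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized planted-signal cohort shared across module tests.

    6 subjects (4 chronic completers), 3 runs per visit, 64 frames: large
    enough for the planted spectral contrast to dominate screening, small
    enough to extract once per test session.
    """
    cfg = CohortConfig(n_subjects=6, n_chronic_completers=4,
                       n_runs_per_visit=3, n_frames=64,
                       lesion_volume_range=(25, 90), seed=123)
    cohort = SyntheticCohort(cfg)
    data = {s.subject_id: extract_subject(s, "subacute") for s in cohort}
    return cohort, data
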