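import numpy as np
import pytest

from advoice.features import FrameGrid, cohort_feature_table
from advoice.prep import extract_speech
from advoice.synth import CohortSpec, null_cohort_spec, simulate_subjects

SR = 44100


@pytest.fixture(scope="session")
def grid():
    return FrameGrid(sample_rate=SR)


def sawtooth(f0: float, duration_s: float, sr: int = SR) -> np.ndarray:
    t = np.arange(int(duration_s * sr)) / sr
    return 2.0 * ((f0 * t) % 1.0) - 1.0


@pytest.fixture(scope="session")
def sawtooth_block():
    """One clean 10-s voiced block at 120 Hz."""
    return sawtooth(120.0, 10.0)


def _cohort_table(spec: CohortSpec):
    recs = list(simulate_subjects(spec))
    table = cohort_feature_table(
        [(r.subject_id, r.group, extract_speech(r)) for r, _ in recs],
        spec.sample_rate, FrameGrid(sample_rate=spec.sample_rate))
    params = {p.subject_id: p for _, p in recs}
    return table, params


@pytest.fixture(scope="session")
def contrast_cohort():
    """Strong-contrast clean cohort: 10 + 10 subjects, 60-s recordings."""
    return _cohort_table(CohortSpec(n_patient=10, n_healthy=10,
                                    duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Calibration cohort: identical zero-scatter profiles, 20 subjects."""
    return _cohort_table(null_cohort_spec(n_per_group=10, duration_s=120.0,
                                          seed=23))
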