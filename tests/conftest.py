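import numpy as np
import pytest

from screenrisk.screening_data import Cohort, ExamRecord, ScreeningHistory
from screenrisk.synthetic_cohort import GeneratorConfig, simulate_cohort


def make_history(subject_id, triples):
    """Build a history from (age, exam_type, state) triples."""
    return ScreeningHistory(
        subject_id=subject_id,
        records=tuple(ExamRecord(time=t, exam_type=e, state=s) for t, e, s in triples),
    )


@pytest.fixture
def tiny_cohort():
    return Cohort(
        histories=[
            make_history("a", [(25.0, "cytology", 1), (28.0, "cytology", 1),
                               (31.0, "histology", 2)]),
            make_history("b", [(22.0, "cytology", 1), (24.5, "cytology", 2),
                               (25.5, "histology", 3), (27.0, "cytology", 2)]),
            make_history("c", [(30.0, "cytology", 1)]),
        ]
    )


def frozen_generator_config(**overrides):
    """Generator with frozen disease dynamics and noise-free exams."""
    zero = [[0.0] * 3 for _ in range(3)]
    identity = np.eye(3).tolist()
    base = dict(
        seed=0,
        n_histories=20,
        age_band_intensities=(zero, zero, zero),
        confusion_cytology=identity,
        confusion_histology=identity,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture
def frozen_config():
    return frozen_generator_config()


@pytest.fixture(scope="session")
def small_default_cohort():
    """A modest default-configuration cohort shared across tests."""
    return simulate_cohort(GeneratorConfig(seed=42, n_histories=400))
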