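import numpy as np
import pytest

from moscato.io_formats import StudyData, SubjectOmicPair


def make_study(n=6, p=8, q=5, m=30, seed=0, signal=True):
    """Small deterministic study: optional planted rank-1 signal where the
    first 2 X features and first 3 G features co-vary with the outcome."""
    rng = np.random.default_rng(seed)
    subjects = []
    # subject-specific co-expression strength drives the outcome; the
    # within-subject covariance of the signal features scales with it
    strength = rng.uniform(0.2, 2.0, size=n)
    for i in range(n):
        base_g = rng.normal(size=(m, p))
        base_x = rng.normal(size=(m, q))
        if signal:
            shared = rng.normal(size=m)
            amp = 1.5 * np.sqrt(strength[i])
            base_g[:, :3] += amp * shared[:, None]
            base_x[:, :2] += amp * shared[:, None]
        subjects.append(SubjectOmicPair(subject_id=f"S{i:03d}",
                                        G=base_g, X=base_x))
    y = strength + 0.1 * rng.normal(size=n) if signal else rng.normal(size=n)
    return StudyData(subjects=subjects, y=y)


@pytest.fixture
def small_study():
    return make_study()
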