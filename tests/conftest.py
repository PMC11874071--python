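import numpy as np
import pytest

from braintraj.io import SubjectRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """Six hand-placed subjects spanning childhood to adulthood."""
    ages = {"case": [7.5, 14.2, 24.0], "control": [8.1, 13.9, 25.5]}
    records = []
    for group, group_ages in ages.items():
        for i, age in enumerate(group_ages):
            records.append(SubjectRecord(subject_id=f"{group[:2]}{i}", group=group,
                                         age=age, sex="male" if i % 2 else "female"))
    return records


def ar1_series(rng, phi, n, burn=50):
    """Seeded AR(1) draw used across entropy tests."""
    eps = rng.standard_normal(n + burn)
    x = np.empty(n + burn)
    x[0] = eps[0]
    for t in range(1, n + burn):
        x[t] = phi * x[t - 1] + eps[t]
    return x[burn:]
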