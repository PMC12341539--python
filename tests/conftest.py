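import numpy as np
import pandas as pd
import pytest

from prejump import CohortMatrix
from prejump.calibration import reference_moment_spec


@pytest.fixture(scope="session")
def calibrated_spec():
    """Moment specification built from the published cohort summary."""
    return reference_moment_spec()


@pytest.fixture()
def small_cohort():
    """A 5-athlete, 3-indicator cohort with strictly positive values."""
    rng = np.random.default_rng(42)
    frame = pd.DataFrame(
        {
            "jump": rng.uniform(2.0, 4.0, size=5),
            "a": rng.uniform(10, 20, size=5),
            "b": rng.uniform(1, 2, size=5),
            "c": rng.uniform(100, 200, size=5),
        }
    )
    return CohortMatrix(frame=frame, criterion="jump")


def brute_force_gra(standard, inspected, p=0.5):
    """Independent pure-Python evaluation of Deng's grey relational grades.

    Loops over sequences and positions with no shared code with the
    implementation under test.
    """
    x0 = list(standard)
    mu0 = sum(x0) / len(x0)
    x0 = [v / mu0 for v in x0]
    rows = []
    for seq in inspected:
        mu = sum(seq) / len(seq)
        rows.append([v / mu for v in seq])
    deltas = [[abs(r[k] - x0[k]) for k in range(len(x0))] for r in rows]
    flat = [d for row in deltas for d in row]
    dmin, dmax = min(flat), max(flat)
    grades = []
    for row in deltas:
        if dmax == 0:
            coeffs = [1.0] * len(row)
        else:
            coeffs = [(dmin + p * dmax) / (d + p * dmax) for d in row]
        grades.append(sum(coeffs) / len(coeffs))
    return grades
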