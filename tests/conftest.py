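import numpy as np
import pandas as pd
import pytest

from glucotrace.ingest import BolusSpec, MouseTimeCourse
from glucotrace.simulate import STUDY_TIMES, default_truth, simulate_mouse


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=0)


@pytest.fixture(scope="session")
def clean_mouse(truth):
    """One noise-free simulated mouse at its cohort means (LFAL, 4 months)."""
    cohort = truth.cohorts[0]
    return simulate_mouse(cohort, BolusSpec(), cohort.body_weight,
                          STUDY_TIMES, measurement_cv=0.0,
                          mouse_id="clean"), cohort


@pytest.fixture
def null_factorial_table():
    """Balanced 2x2x2 table of pure noise (n=4 per cell)."""
    rng = np.random.default_rng(7)
    rows = []
    for d in ("LF", "HFS"):
        for p in ("AL", "DR"):
            for a in (4, 15):
                for i in range(4):
                    rows.append(dict(mouse_id=f"{d}{p}{a}_{i}", diet=d,
                                     provision=p, age_months=a,
                                     response=rng.normal()))
    return pd.DataFrame(rows)


def _balanced_table(rng, n=8, diet_shift=0.0, ages=(4, 15), sigma=1.0):
    """Balanced factorial noise table with an optional Diet main effect."""
    rows = []
    for d in ("LF", "HFS"):
        for p in ("AL", "DR"):
            for a in ages:
                mu = diet_shift if d == "HFS" else 0.0
                for i in range(n):
                    rows.append(dict(mouse_id=f"{d}{p}{a}_{i}", diet=d,
                                     provision=p, age_months=a,
                                     response=mu + sigma * rng.normal()))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def balanced_table():
    """Factory for balanced 2x2xK factorial tables."""
    return _balanced_table
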