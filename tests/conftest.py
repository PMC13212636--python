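import numpy as np
import pandas as pd
import pytest

from ctbenefit.cohort import COLUMN_ORDER, TrialCohort
from ctbenefit.simulate import default_hermes_config, generate_cohort, scale_trials


def brute_force_concordance(goodness, score):
    """O(n^2) oracle: over pairs with unequal goodness, fraction where the
    better one has the strictly higher score, score ties counted 0.5."""
    goodness = np.asarray(goodness, float)
    score = np.asarray(score, float)
    num = den = 0.0
    n = goodness.size
    for i in range(n):
        for j in range(i + 1, n):
            if goodness[i] == goodness[j]:
                continue
            den += 1
            hi, lo = (i, j) if goodness[i] > goodness[j] else (j, i)
            if score[hi] > score[lo]:
                num += 1
            elif score[hi] == score[lo]:
                num += 0.5
    return num / den


def tiny_frame(n=6, seed=0):
    """Hand-sized complete patient table covering every column."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "trial_id": ["T1"] * (n // 2) + ["T2"] * (n - n // 2),
            "evt": [1, 0] * (n // 2) + [1] * (n % 2),
            "mrs90": rng.integers(0, 7, n),
            "age": rng.uniform(40, 90, n).round(1),
            "nihss": rng.integers(2, 30, n),
            "sbp": rng.uniform(100, 190, n).round(0),
            "glucose": rng.uniform(80, 200, n).round(0),
            "prestroke_mrs": rng.integers(0, 3, n),
            "diabetes": rng.integers(0, 2, n),
            "iv_alteplase": rng.integers(0, 2, n),
            "onset_to_groin": rng.uniform(90, 400, n).round(0),
            "aspects": rng.integers(5, 11, n),
            "occlusion": rng.choice(["ICA_ICAT", "M1", "M2"], n),
            "collateral": rng.integers(0, 4, n),
            "wml_volume": rng.uniform(0, 10, n).round(2),
            "bpf": rng.uniform(72, 88, n).round(2),
            "old_infarct_volume": rng.uniform(0, 5, n).round(2),
            "icac": rng.choice(["NONE", "INTIMAL", "MEDIAL"], n),
        }
    )[COLUMN_ORDER]


@pytest.fixture
def tiny_cohort():
    return TrialCohort(tiny_frame(8, seed=3))


@pytest.fixture(scope="session")
def default_config():
    return default_hermes_config()


@pytest.fixture(scope="session")
def complete_cohort(default_config):
    """Default-size 7-trial cohort with no missingness (shared, read-only)."""
    return generate_cohort(scale_trials(default_config, 1391, missing_rate=0.0),
                           seed=42)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """n=10000 complete cohort for recovery-style checks (shared, read-only)."""
    return generate_cohort(scale_trials(default_config, 10_000, missing_rate=0.0),
                           seed=7)
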