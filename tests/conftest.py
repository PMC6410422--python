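import numpy as np
import pandas as pd
import pytest

from metsgxe import constants as C
from metsgxe.phenotyping import phenotype_cohort
from metsgxe.simulate import SimulationConfig, simulate_cohort

# Balanced-exposure AAM category mix used for calibration-style experiments,
# where the early group must be large enough for the chi-square reference
# to apply per cohort realization (see docs/methods.md).
BALANCED_AAM_PROBS = (0.5, 0.1, 0.1, 0.1, 0.1, 0.1)


def make_cohort(aam, seed=0, n=None, **columns):
    """Hand-built raw cohort table with sensible filler columns."""
    aam = np.asarray(aam, dtype=float)
    n = len(aam)
    rng = np.random.default_rng(seed)
    base = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "aam": aam,
        "sbp": rng.normal(118, 16, n),
        "dbp": rng.normal(73, 10, n),
        "fg": rng.normal(92, 16, n),
        "fi": rng.normal(9, 4, n).clip(0.5),
        "wc": rng.normal(80, 9, n),
        "tg": rng.normal(130, 80, n),
        "hdl": rng.normal(52, 11, n),
        "antihypertensive_med": np.zeros(n, dtype=int),
        "antidiabetic_med": np.zeros(n, dtype=int),
        "age": rng.uniform(40, 69, n),
        "area": rng.integers(0, 2, n),
        "income": rng.integers(0, 3, n),
        "education": rng.integers(0, 3, n),
        "crp": rng.lognormal(0.0, 0.7, n),
        "smoking": np.zeros(n, dtype=int),
        "alcohol": rng.exponential(1.4, n),
        "obs_score": rng.normal(9.1, 2.5, n),
    }
    base.update(columns)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def phenotyped_cohort():
    """Medium synthetic cohort, fully phenotyped, shared across tests."""
    cfg = SimulationConfig(n_subjects=3000, n_snps=1, seed=101)
    cohort = simulate_cohort(cfg)
    out, _ = phenotype_cohort(cohort)
    return out
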