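"""Shared fixtures: background table, injected excess hazard, synthetic cohorts.

The study conditions mirror a registry cohort: diagnoses uniform over
1975-2016 with administrative censoring at end of 2016, age at diagnosis
normal(63, 13) truncated to [3, 99], 52.3% male, Gompertz-Makeham background
mortality, and an injected trigam excess hazard with AUC
0.455 + 0.05 * 2 = 0.555.  Heavier cohorts are session-scoped so the suite
generates them once.
"""

import numpy as np
import pytest

import lifetimerisk as lr

TRUE_AUC = 0.555
N_LARGE = 20_000


@pytest.fixture(scope="session")
def gm_table():
    return lr.make_synthetic_lifetable()


@pytest.fixture(scope="session")
def study_trigam():
    return lr.TrigamParams(A=0.455, k=2.0, theta=3.0, H=0.05, p_c=3.0, w=2.0)


@pytest.fixture(scope="session")
def study_cohort(gm_table, study_trigam):
    """n=20,000 cases with the true excess hazard, no misreporting."""
    cfg = lr.GenConfig(n_cases=N_LARGE, seed=1, trigam=study_trigam)
    return lr.generate_cohort(cfg, gm_table)


@pytest.fixture(scope="session")
def misreported_cohorts(gm_table, study_trigam, study_cohort):
    """Matched-seed cohorts at misreport_frac 0, 0.15 and 0.3."""
    out = {0.0: study_cohort}
    for frac in (0.15, 0.3):
        cfg = lr.GenConfig(n_cases=N_LARGE, seed=1, trigam=study_trigam, misreport_frac=frac)
        out[frac] = lr.generate_cohort(cfg, gm_table)
    return out


@pytest.fixture(scope="session")
def null_cohort(gm_table):
    """n=10,000 cases with zero injected excess hazard."""
    cfg = lr.GenConfig(n_cases=10_000, seed=7, trigam=lr.TrigamParams())
    return lr.generate_cohort(cfg, gm_table)


@pytest.fixture(scope="session")
def zero_background_cohort(study_trigam):
    """Immortal background: every death is a cancer death; long horizon so the
    empirical death probability approximates the t -> infinity cure fraction."""
    table = lr.make_synthetic_lifetable(makeham_a=0.0, gompertz_b=0.0, gompertz_c=0.1)
    cfg = lr.GenConfig(n_cases=50_000, seed=13, trigam=study_trigam,
                       age_mean=10.0, age_sd=3.0, age_range=(3.0, 20.0),
                       dx_year_range=(1975.0, 1976.0), study_end=2070.0)
    return lr.generate_cohort(cfg, table)


@pytest.fixture(scope="session")
def small_cohort(gm_table, study_trigam):
    cfg = lr.GenConfig(n_cases=400, seed=11, trigam=study_trigam)
    return lr.generate_cohort(cfg, gm_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
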