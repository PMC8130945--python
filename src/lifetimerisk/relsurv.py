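"""Expected survival by matched-control simulation, and relative survival.

For each case, ``k`` disease-free "normal" counterparts with the same sex,
age and calendar year are walked forward through the background life table
one year at a time: in each step death occurs with probability
``1 - exp(-m)`` for that Lexis cell's rate ``m``, and a death's time within
the year is drawn uniformly.  Age and year both advance by one year per
step, so rates update along the simulant's Lexis diagonal.  The empirical
survival of the simulated death times is the expected survival of a matched
general-population cohort, and relative survival is observed OS divided by
it.  Because it uses all-cause observed survival only, relative survival is
untouched by cause-of-death misclassification.

The yearly-step scheme is deliberately cruder than the exact inversion used
by the synthetic generator: it reproduces the registry-analysis convention,
and its small discretisation bias is bounded in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .estimators import StepSurvival
from .lifetables import LifeTable, _sex_index

logger = logging.getLogger(__name__)

AGE_CAP = 120.0  # forced death at this age guarantees termination


@dataclass
class ExpectedCohort:
    """Simulated matched controls: one row per simulant."""

    df: pd.DataFrame  # columns: case_id, sex, age_start, year_start, death_time
    k_per_case: int

    def __post_init__(self):
        if (self.df["death_time"] <= 0).any():
            raise ValueError("simulated death times must be positive")


def sim_expected(cohort: Cohort, table: LifeTable, k: int = 3, seed: int = 0) -> ExpectedCohort:
    """Simulate ``k`` matched controls per case through the life table."""
    if k < 1:
        raise ValueError("k must be at least 1")
    rng = np.random.default_rng(seed)
    base = cohort.df
    n = len(base) * k
    case_id = np.repeat(base["id"].to_numpy(), k)
    sex = np.repeat(base["sex"].to_numpy(), k)
    age0 = np.repeat(base["age_dx"].to_numpy(dtype=float), k)
    year0 = np.repeat(base["year_dx"].to_numpy(dtype=float), k)
    sex_idx = np.array([_sex_index(s) for s in base["sex"]])
    sex_i = np.repeat(sex_idx, k)

    death_time = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)
    step = 0
    max_steps = int(np.ceil(AGE_CAP)) + 1
    while alive.any() and step < max_steps:
        idx = np.flatnonzero(alive)
        age = age0[idx] + step
        capped = age >= AGE_CAP
        if capped.any():
            cap_idx = idx[capped]
            death_time[cap_idx] = AGE_CAP - age0[cap_idx]
            alive[cap_idx] = False
            idx = idx[~capped]
            age = age[~capped]
        if len(idx) == 0:
            break
        ai = np.clip(np.floor(age).astype(int) - table.age_min, 0, table.rates.shape[1] - 1)
        yi = np.clip(np.floor(year0[idx] + step).astype(int) - table.year_min,
                     0, table.rates.shape[2] - 1)
        m = table.rates[sex_i[idx], ai, yi]
        u = rng.random(len(idx))
        dies = u < 1.0 - np.exp(-m)
        if dies.any():
            within = rng.random(int(dies.sum()))
            die_idx = idx[dies]
            death_time[die_idx] = step + within
            alive[die_idx] = False
        step += 1

    df = pd.DataFrame({
        "case_id": case_id, "sex": sex, "age_start": age0, "year_start": year0,
        "death_time": death_time,
    })
    return ExpectedCohort(df, k_per_case=k)


def expected_survival(exp_cohort: ExpectedCohort, t_grid=None) -> StepSurvival:
    """Empirical survival curve of the simulated death times (no censoring).

    No CI is attached: with high ``k`` the simulation error is negligible
    relative to the observed arm; ``meta['k']`` records the multiplier.
    """
    dtimes = np.sort(exp_cohort.df["death_time"].to_numpy(dtype=float))
    if len(dtimes) == 0:
        raise ValueError("empty expected cohort")
    u, counts = np.unique(dtimes, return_counts=True)
    n = len(dtimes)
    n_at_risk = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    surv = 1.0 - np.cumsum(counts) / n
    curve = StepSurvival(u, surv, surv, surv, n_at_risk, counts, kind="survival",
                         meta={"k": exp_cohort.k_per_case, "ci": "omitted"})
    if t_grid is not None:
        return curve.eval_at(t_grid)
    return curve


@dataclass
class RelSurvCurve:
    """Relative survival RS(t) = S_obs(t) / S_exp(t) on a grid.

    Values may exceed 1.  CI bounds divide the observed KM bounds by the
    (near-deterministic) expected curve.
    """

    frame: pd.DataFrame  # time, value, lo, hi, extrapolated
    k: int

    @property
    def times(self):
        return self.frame["time"].to_numpy()

    @property
    def values(self):
        return self.frame["value"].to_numpy()

    def eval_at(self, t_grid) -> pd.DataFrame:
        t_grid = np.atleast_1d(t_grid)
        out = self.frame.set_index("time").reindex(t_grid)
        if out["value"].isna().any():
            raise KeyError("requested time not on the relative-survival grid")
        return out.reset_index()

    def to_tsv(self, path):
        f = self.frame.copy()
        f["k"] = self.k
        f.to_csv(path, sep="\t", index=False)


def relative_survival(observed: StepSurvival, expected: StepSurvival, t_grid) -> RelSurvCurve:
    """Ratio of observed to expected survival on ``t_grid``.

    Grid points where expected survival is 0 are dropped with a warning.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    obs = observed.eval_at(t_grid)
    exp_ = expected.eval_at(t_grid)
    s_exp = exp_["value"].to_numpy()
    ok = s_exp > 0
    if not ok.all():
        logger.warning("expected survival is 0 at %d grid point(s); dropped", int((~ok).sum()))
    frame = pd.DataFrame({
        "time": t_grid[ok],
        "value": obs["value"].to_numpy()[ok] / s_exp[ok],
        "lo": obs["lo"].to_numpy()[ok] / s_exp[ok],
        "hi": obs["hi"].to_numpy()[ok] / s_exp[ok],
        "extrapolated": (obs["extrapolated"] | exp_["extrapolated"]).to_numpy()[ok],
    })
    k = expected.meta.get("k", 0) if hasattr(expected, "meta") else 0
    return RelSurvCurve(frame, k=k)
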