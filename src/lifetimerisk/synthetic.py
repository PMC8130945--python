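"""Synthetic registry cohorts with known background and excess mortality.

The generator draws demographics (sex, age and calendar year at diagnosis)
and then simulates each case's time to death under the total hazard

    lambda(t) = m(sex, age_dx + t, year_dx + t) + h_trigam(t)

where ``m`` is the background life-table hazard (piecewise constant on unit
Lexis cells) and ``h_trigam`` a known injected excess hazard.  Sampling
inverts the exact cumulative hazard — closed form within each segment between
age/year boundaries and triangle breakpoints — so recovery oracles have
closed forms: with zero background, the probability of ever dying of the
cancer is exactly ``1 - exp(-AUC)``.

At the sampled death time the cause is attributed to the cancer with
probability ``h(t) / lambda(t)`` (competing-risks identity); deaths after the
administrative study end are censored alive.  Optionally a fraction of cancer
deaths is relabelled to other causes, emulating registry under-reporting of
metastatic deaths.  Demographics, survival and misreporting use independent
seeded substreams, so two runs with the same seed and different
``misreport_frac`` differ only in cause-of-death labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .cohort import Cohort
from .lifetables import LifeTable
from .trigam import TrigamParams

# Study-condition defaults: registry diagnoses 1975-2016 with administrative
# censoring at the end of 2016, ages at diagnosis centred on 63 (range 3-99),
# and a slight male excess.
DEFAULT_AGE_MEAN = 63.0
DEFAULT_AGE_SD = 13.0
DEFAULT_AGE_RANGE = (3.0, 99.0)
DEFAULT_SEX_RATIO = 0.523
DEFAULT_DX_YEARS = (1975.0, 2017.0)
DEFAULT_STUDY_END = 2017.0


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the synthetic-registry generator."""

    n_cases: int
    seed: int
    trigam: TrigamParams = field(default_factory=TrigamParams)
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    age_range: tuple = DEFAULT_AGE_RANGE
    sex_ratio: float = DEFAULT_SEX_RATIO
    dx_year_range: tuple = DEFAULT_DX_YEARS
    misreport_frac: float = 0.0
    study_end: float = DEFAULT_STUDY_END

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be at least 1")
        if not 0.0 <= self.misreport_frac <= 1.0:
            raise ValueError("misreport_frac must be in [0, 1]")
        if self.age_range[0] < 0:
            raise ValueError("age distribution must have nonnegative support")
        if not self.dx_year_range[0] < self.dx_year_range[1] <= self.study_end:
            raise ValueError("need dx_year_range[0] < dx_year_range[1] <= study_end")

    def to_json(self, path=None):
        d = asdict(self)
        d["trigam"] = asdict(self.trigam)
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s):
        d = json.loads(s)
        d["trigam"] = TrigamParams(**d["trigam"])
        d["age_range"] = tuple(d["age_range"])
        d["dx_year_range"] = tuple(d["dx_year_range"])
        return cls(**d)


def _case_boundaries(age0, year0, censor, trig_bps):
    """Segment boundaries in t: unit age/year crossings and trigam breakpoints."""
    a0 = np.floor(age0)
    y0 = np.floor(year0)
    t_age = np.arange(a0 + 1.0, age0 + censor + 1e-12) - age0
    t_year = np.arange(y0 + 1.0, year0 + censor + 1e-12) - year0
    b = np.concatenate(([0.0, censor], t_age, t_year, trig_bps[trig_bps < censor]))
    b = np.unique(b[(b >= 0.0) & (b <= censor)])
    # guard against duplicates closer than fp noise
    return b[np.concatenate(([True], np.diff(b) > 1e-12))]


def _simulate_case(rng, trig: TrigamParams, table: LifeTable, sex, age0, year0, censor):
    """Return (futime, died, cancer) for one case by exact hazard inversion."""
    b = _case_boundaries(age0, year0, censor, trig.breakpoints())
    left = b[:-1]
    m = np.atleast_1d(table.get_rate(sex, age0 + left, year0 + left))
    cum_bg = np.concatenate(([0.0], np.cumsum(m * np.diff(b))))
    cum_h = trig.cum_hazard(b)
    total = cum_bg + cum_h

    target = rng.exponential()
    if target >= total[-1]:
        return censor, False, False
    j = int(np.searchsorted(total, target, side="right")) - 1
    j = min(j, len(b) - 2)
    rem = target - total[j]
    mj = m[j]
    trig_inc = cum_h[j + 1] - cum_h[j]
    if trig_inc <= 1e-14:
        t = b[j] + (rem / mj if mj > 0 else 0.0)
    else:
        chj = cum_h[j]

        def g(t):
            return mj * (t - b[j]) + (trig.cum_hazard(t) - chj) - rem

        t = brentq(g, b[j], b[j + 1], xtol=1e-12)
    t = min(max(t, np.nextafter(0.0, 1.0)), censor)
    h = trig.hazard(t)
    lam = mj + h
    cancer = bool(rng.random() < (h / lam if lam > 0 else 0.0))
    return t, True, cancer


def generate_cohort(cfg: GenConfig, table: LifeTable) -> Cohort:
    """Generate a synthetic cohort; fully reproducible from ``cfg.seed``."""
    y_lo, y_hi = cfg.dx_year_range
    if np.floor(y_lo) < table.year_min or np.floor(y_hi - 1e-9) > table.year_max:
        raise ValueError(
            f"life table years [{table.year_min}, {table.year_max}] do not cover "
            f"diagnosis years [{y_lo}, {y_hi})"
        )
    demo, surv, mis = (np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3))

    n = cfg.n_cases
    male = demo.random(n) < cfg.sex_ratio
    lo, hi = cfg.age_range
    a = (lo - cfg.age_mean) / cfg.age_sd
    bnd = (hi - cfg.age_mean) / cfg.age_sd
    age_dx = truncnorm.rvs(a, bnd, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=demo)
    year_dx = demo.uniform(y_lo, y_hi, n)
    censor = cfg.study_end - year_dx

    rows = []
    for i in range(n):
        sex = "male" if male[i] else "female"
        t, died, cancer = _simulate_case(surv, cfg.trigam, table, sex, age_dx[i], year_dx[i], censor[i])
        if died:
            status = "dead_cancer" if cancer else "dead_other"
        else:
            status = "alive"
        rows.append((f"case{i:06d}", sex, age_dx[i], year_dx[i], t, status))

    import pandas as pd

    df = pd.DataFrame(rows, columns=["id", "sex", "age_dx", "year_dx", "futime", "status"])
    # synthetic cases carry in-scope tumour codes so the ICD-O-3 filter retains them
    df["morph"] = 8720
    df["site"] = "C69.3"

    u = mis.random(n)
    flip = (df["status"] == "dead_cancer") & (u < cfg.misreport_frac)
    df.loc[flip, "status"] = "dead_other"
    return Cohort(df, study_end=cfg.study_end)


def true_cancer_death_prob(cfg: GenConfig, table: LifeTable, sex="male", age0=None,
                           year0=None, horizon=None, n_grid=20000) -> float:
    """Oracle: P(death from cancer) for one covariate profile by quadrature.

    Integrates S(t) h(t) dt on a fine grid, where S is survival under the
    total hazard.  Used by tests as an independent check on the generator.
    """
    trig = cfg.trigam
    age0 = cfg.age_mean if age0 is None else age0
    year0 = cfg.dx_year_range[0] if year0 is None else year0
    horizon = (cfg.study_end - year0) if horizon is None else horizon
    t = np.linspace(0, horizon, n_grid + 1)
    mid = 0.5 * (t[:-1] + t[1:])
    dt = np.diff(t)
    m = table.get_rate(sex, age0 + mid, year0 + mid)
    h = trig.hazard(mid)
    cum = np.concatenate(([0.0], np.cumsum((m + h) * dt)))
    s_mid = np.exp(-0.5 * (cum[:-1] + cum[1:]))
    return float(np.sum(s_mid * h * dt))
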