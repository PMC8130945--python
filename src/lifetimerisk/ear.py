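"""Excess absolute risk: Lexis person-year tabulation and the trigam fit.

Follow-up after diagnosis is pooled across patients into time-since-diagnosis
intervals.  Within an interval each trajectory is further split at integer
age and calendar-year boundaries (unit Lexis cells) so that expected deaths
accrue exactly as sum of rate x duration; observed deaths O are all-cause, so
nothing here depends on cause-of-death labels.  Per interval the table
reports person-years PY, observed and expected deaths, the relative risk
RR = O/E and the excess absolute risk EAR = (O - E)/PY, with exact Poisson
(Garwood) intervals on O.

The parametric stage fits the trigam excess hazard (gamma wave + triangle
wave, see :mod:`lifetimerisk.trigam`) to the binned counts by maximising the
Poisson likelihood with mean E_i + h(t_mid,i) * PY_i.  The fitted area under
the excess hazard is the expected number of lifetime excess deaths per
person; lifetime risk of death from the cancer follows as 1 - exp(-AUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort
from .lifetables import LifeTable, _sex_index
from .trigam import TrigamParams

logger = logging.getLogger(__name__)

LAMBDA_FLOOR = 1e-10


def default_breaks(max_time: float = 42.0) -> np.ndarray:
    """Interval boundaries widening with time since diagnosis.

    Half-year first bin, yearly to 10, two-yearly to 20, then five-yearly:
    longer late intervals pool enough deaths for stable late-risk estimates.
    """
    five_yearly = np.arange(25.0, max_time + 1e-9, 5.0)
    five_yearly = five_yearly[five_yearly <= max_time - 5.0 + 1e-9]
    b = np.concatenate((
        [0.0, 0.5],
        np.arange(1.0, 10.0 + 1e-9),
        np.arange(12.0, 20.0 + 1e-9, 2.0),
        five_yearly,
        [max_time],
    ))
    return np.unique(b)


@dataclass
class EarTable:
    """Per-interval O, E, PY, RR and EAR with 95% intervals."""

    df: pd.DataFrame
    breaks: np.ndarray

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def total_py(self) -> float:
        return float(self.df["PY"].sum())

    @property
    def total_deaths(self) -> int:
        return int(self.df["O"].sum())


def _garwood(o: np.ndarray):
    """Exact Poisson 95% bounds for observed counts."""
    o = np.asarray(o, dtype=float)
    lo = np.where(o > 0, stats.chi2.ppf(0.025, 2 * np.maximum(o, 1)) / 2.0, 0.0)
    hi = stats.chi2.ppf(0.975, 2 * (o + 1)) / 2.0
    return lo, hi


def tabulate_ear(cohort: Cohort, table: LifeTable, breaks=None) -> EarTable:
    """Tally person-years, observed and expected deaths per interval.

    Expected deaths integrate the background hazard along each case's Lexis
    diagonal exactly (piecewise-constant rates over unit age x year cells).
    A case whose follow-up extends past the last break raises, naming it.
    """
    breaks = default_breaks() if breaks is None else np.asarray(breaks, dtype=float)
    if len(breaks) < 2 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing with at least two values")
    nb = len(breaks) - 1
    py = np.zeros(nb)
    expd = np.zeros(nb)
    obs = np.zeros(nb, dtype=int)
    tsum = np.zeros(nb)

    df = cohort.df
    sex_idx = df["sex"].map(lambda s: _sex_index(s)).to_numpy()
    age0 = df["age_dx"].to_numpy(dtype=float)
    year0 = df["year_dx"].to_numpy(dtype=float)
    fut = df["futime"].to_numpy(dtype=float)
    dead = (df["status"] != "alive").to_numpy()
    ids = df["id"].to_numpy()

    too_long = fut > breaks[-1] + 1e-9
    if too_long.any():
        raise ValueError(
            f"case {ids[np.argmax(too_long)]!r} has follow-up {fut[too_long].max():.3f} y "
            f"beyond the last break {breaks[-1]}"
        )

    n_age, n_year = table.rates.shape[1], table.rates.shape[2]
    for i in range(len(df)):
        f = fut[i]
        inner = breaks[(breaks > 0) & (breaks < f)]
        t_age = np.arange(np.floor(age0[i]) + 1.0, age0[i] + f) - age0[i]
        t_year = np.arange(np.floor(year0[i]) + 1.0, year0[i] + f) - year0[i]
        b = np.unique(np.concatenate(([0.0, f], inner, t_age, t_year)))
        b = b[(b >= 0.0) & (b <= f)]
        left, dur = b[:-1], np.diff(b)
        ai = np.clip(np.floor(age0[i] + left).astype(int) - table.age_min, 0, n_age - 1)
        yi = np.clip(np.floor(year0[i] + left).astype(int) - table.year_min, 0, n_year - 1)
        m = table.rates[sex_idx[i], ai, yi]
        bins = np.clip(np.searchsorted(breaks, left, side="right") - 1, 0, nb - 1)
        np.add.at(py, bins, dur)
        np.add.at(expd, bins, m * dur)
        np.add.at(tsum, bins, (left + dur / 2.0) * dur)
        if dead[i]:
            k = min(int(np.searchsorted(breaks, f, side="right")) - 1, nb - 1)
            obs[k] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mid = np.where(py > 0, tsum / py, 0.5 * (breaks[:-1] + breaks[1:]))
        o_lo, o_hi = _garwood(obs)
        rr = np.where(expd > 0, obs / expd, np.nan)
        rr_lo = np.where(expd > 0, o_lo / expd, np.nan)
        rr_hi = np.where(expd > 0, o_hi / expd, np.nan)
        ear = np.where(py > 0, (obs - expd) / py, np.nan)
        ear_lo = np.where(py > 0, (o_lo - expd) / py, np.nan)
        ear_hi = np.where(py > 0, (o_hi - expd) / py, np.nan)

    out = pd.DataFrame({
        "t_lo": breaks[:-1], "t_hi": breaks[1:], "t_mid": t_mid,
        "PY": py, "O": obs, "E": expd,
        "RR": rr, "RR_lo": rr_lo, "RR_hi": rr_hi,
        "EAR": ear, "EAR_lo": ear_lo, "EAR_hi": ear_hi,
    })
    return EarTable(out, breaks)


# ---------------------------------------------------------------------------
# Trigam fit

@dataclass
class TrigamFit:
    """Result of the Poisson trigam fit."""

    params: TrigamParams
    loglik: float
    auc: float
    converged: bool
    n_starts: int
    fix_triangle: bool

    @property
    def lifetime_risk(self) -> float:
        return lifetime_risk_from_auc(self.auc)

    def report(self) -> str:
        p = self.params
        lines = [
            f"A {p.A:.6g}", f"k {p.k:.6g}", f"theta {p.theta:.6g}",
            f"H {p.H:.6g}", f"p_c {p.p_c:.6g}", f"w {p.w:.6g}",
            f"AUC {self.auc:.6g}", f"loglik {self.loglik:.6g}",
            f"converged {self.converged}", f"starts {self.n_starts}",
            f"fix_triangle {self.fix_triangle}",
        ]
        return "\n".join(lines)


def _params_from_vector(x, fix_triangle):
    if fix_triangle:
        return TrigamParams(A=x[0], k=x[1], theta=x[2], H=0.0)
    return TrigamParams(A=x[0], k=x[1], theta=x[2], H=x[3], p_c=x[4], w=x[5])


def fit_trigam(ear: EarTable, init: TrigamParams | None = None,
               fix_triangle: bool = False, n_starts: int = 5, seed: int = 0) -> TrigamFit:
    """Fit the trigam excess hazard to an EAR table by Poisson likelihood.

    The per-interval Poisson mean is E_i + h(t_mid,i) * PY_i (floored at
    1e-10); parameters are box-constrained nonnegative and the optimiser is
    restarted from ``n_starts`` seeded initial points, keeping the best
    converged solution.  ``fix_triangle`` drops the triangle wave (H = 0),
    for sparse or young-age cohorts where it is not detectable.
    """
    sub = ear.df[ear.df["PY"] > 0]
    if len(sub) < 6:
        raise ValueError("need at least 6 intervals with person-years to fit")
    o = sub["O"].to_numpy(dtype=float)
    e = sub["E"].to_numpy(dtype=float)
    pyr = sub["PY"].to_numpy(dtype=float)
    tmid = sub["t_mid"].to_numpy(dtype=float)
    tmax = float(ear.breaks[-1])

    def nll(x):
        p = _params_from_vector(x, fix_triangle)
        lam = np.maximum(e + p.hazard(tmid) * pyr, LAMBDA_FLOOR)
        return float(np.sum(lam - o * np.log(lam)))

    if init is None:
        init = TrigamParams(A=0.5, k=2.0, theta=3.0, H=0.02, p_c=3.0, w=2.0)
    full_bounds = [(0.0, 50.0), (0.2, 30.0), (0.1, 60.0),
                   (0.0, 5.0), (0.0, tmax), (0.1, tmax)]
    if fix_triangle:
        bounds = full_bounds[:3]
        x0s = [np.array([init.A, init.k, init.theta])]
    else:
        bounds = full_bounds
        x0s = [np.array([init.A, init.k, init.theta, init.H, init.p_c, init.w])]
    rng = np.random.default_rng(seed)
    while len(x0s) < n_starts:
        x = np.array([rng.uniform(0.05, 2.0), rng.uniform(0.5, 6.0), rng.uniform(0.5, 10.0),
                      rng.uniform(0.0, 0.1), rng.uniform(0.5, 8.0), rng.uniform(0.5, 6.0)])
        x0s.append(x[:3] if fix_triangle else x)

    best = None
    any_converged = False
    for x0 in x0s:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            # prefer converged solutions at equal or better objective
            if res.success or best is None or res.fun < best.fun - 1e-9:
                best = res
        any_converged = any_converged or bool(res.success)
    if not any_converged:
        raise RuntimeError(
            f"trigam fit failed to converge from any of {len(x0s)} starts; "
            f"best objective {best.fun:.6g} at {best.x}"
        )
    params = _params_from_vector(best.x, fix_triangle)
    return TrigamFit(params=params, loglik=-best.fun, auc=params.auc,
                     converged=bool(best.success), n_starts=len(x0s),
                     fix_triangle=fix_triangle)


# ---------------------------------------------------------------------------
# AUC -> lifetime risk

def lifetime_risk_from_auc(auc: float) -> float:
    """Lifetime probability of death from the cancer: 1 - exp(-AUC)."""
    if auc < 0:
        raise ValueError("AUC must be nonnegative")
    return float(-np.expm1(-auc))


def survival_from_auc(auc: float) -> float:
    """Companion: probability of never dying of the cancer, exp(-AUC)."""
    if auc < 0:
        raise ValueError("AUC must be nonnegative")
    return float(np.exp(-auc))
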