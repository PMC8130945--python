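"""Nonparametric survival machinery: Kaplan-Meier and Aalen-Johansen.

Overall survival (OS) treats any death as the event; metastasis-free
survival (MFS) treats only cancer deaths as events, censoring other-cause
deaths.  The Aalen-Johansen estimator gives the cause-specific cumulative
incidence of death in the presence of the competing cause; at every event
time the two cause curves and the all-cause Kaplan-Meier estimate sum to one
exactly.

Confidence intervals are 95% pointwise: Greenwood variance with the
log(-log) transform for KM (via lifelines), and the standard
counting-process variance with the log(-log(1-F)) transform for cumulative
incidence — both keep bounds inside [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class StepSurvival:
    """A right-continuous step estimate with pointwise 95% bounds.

    ``kind`` is "survival" (nonincreasing from 1) or "incidence"
    (nondecreasing from 0).  ``times`` holds the event times at which the
    estimate changes; evaluation before the first event time returns the
    baseline (1 or 0).
    """

    times: np.ndarray
    values: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    kind: str = "survival"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("times", "values", "lo", "hi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        self.n_event = np.asarray(self.n_event, dtype=int)
        if self.kind not in ("survival", "incidence"):
            raise ValueError("kind must be 'survival' or 'incidence'")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # degenerate bounds for NaNs (e.g. at S = 0), then clip into [0, 1]
        self.lo = np.clip(np.where(np.isfinite(self.lo), self.lo, self.values), 0.0, 1.0)
        self.hi = np.clip(np.where(np.isfinite(self.hi), self.hi, self.values), 0.0, 1.0)
        self.lo = np.minimum(self.lo, self.values)
        self.hi = np.maximum(self.hi, self.values)

    @property
    def baseline(self) -> float:
        return 1.0 if self.kind == "survival" else 0.0

    def eval_at(self, t_grid) -> pd.DataFrame:
        """Right-continuous evaluation on a grid, with CIs.

        Times past the last event time return the last value, flagged
        ``extrapolated`` — late read-offs sit near the data's edge.
        """
        t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
        if np.any(t_grid < 0):
            raise ValueError("t_grid must be nonnegative")
        idx = np.searchsorted(self.times, t_grid, side="right") - 1
        base = idx < 0
        idx = np.clip(idx, 0, max(len(self.times) - 1, 0))

        def pick(arr, fill):
            if len(self.times) == 0:
                return np.full(len(t_grid), fill)
            return np.where(base, fill, arr[idx])

        b = self.baseline
        last = self.times[-1] if len(self.times) else np.inf
        return pd.DataFrame({
            "time": t_grid,
            "value": pick(self.values, b),
            "lo": pick(self.lo, b),
            "hi": pick(self.hi, b),
            "extrapolated": t_grid > last,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "estimate": self.values, "lo": self.lo, "hi": self.hi,
            "n_risk": self.n_risk, "n_event": self.n_event,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def eval_at(curve: StepSurvival, t_grid) -> pd.DataFrame:
    """Module-level alias for :meth:`StepSurvival.eval_at`."""
    return curve.eval_at(t_grid)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_fit(times, events) -> StepSurvival:
    """Product-limit estimate with Greenwood variance and log(-log) 95% CI.

    Ties are grouped; deaths precede censorings at identical times.  An
    all-censored input yields a flat S = 1 curve with a logged warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one observation")
    if np.any(times <= 0):
        raise ValueError("durations must be positive")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    if events.sum() == 0:
        logger.warning("all observations censored: survival is identically 1")
        e = np.array([])
        return StepSurvival(e, e, e, e, e, e, kind="survival")

    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(times, events)
    et = kmf.event_table
    dt = et.index[(et["observed"] > 0) & (et.index > 0)]
    sf = kmf.survival_function_.iloc[:, 0].loc[dt].to_numpy()
    ci = kmf.confidence_interval_.loc[dt]
    return StepSurvival(
        times=dt.to_numpy(dtype=float),
        values=sf,
        lo=ci.iloc[:, 0].to_numpy(),
        hi=ci.iloc[:, 1].to_numpy(),
        n_risk=et.loc[dt, "at_risk"].to_numpy(),
        n_event=et.loc[dt, "observed"].to_numpy(),
        kind="survival",
    )


def code_events(cohort: Cohort, metric: str):
    """Event coding for OS or MFS.

    OS counts any death as the event.  MFS proxies time to metastasis by the
    time of death from the cancer, so only cancer deaths are events and
    other-cause deaths are right-censored.
    """
    metric = metric.upper()
    status = cohort.df["status"]
    durations = cohort.df["futime"].to_numpy(dtype=float)
    if metric == "OS":
        events = status.isin(("dead_cancer", "dead_other")).to_numpy(dtype=int)
    elif metric == "MFS":
        events = (status == "dead_cancer").to_numpy(dtype=int)
    else:
        raise ValueError("metric must be 'OS' or 'MFS'")
    return durations, events


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence

def cif_fit(times, cause):
    """Aalen-Johansen cumulative incidence for two competing causes.

    ``cause`` holds 0 (censored), 1 (cancer) or 2 (other).  Returns the pair
    of incidence curves (cause 1, cause 2) on the common grid of all-cause
    death times; at every such time CIF1 + CIF2 + KM equals 1 exactly.
    Variance is the standard counting-process estimator, evaluated with
    cumulative sums; the 95% CI uses the log(-log(1-F)) transform.
    """
    times = np.asarray(times, dtype=float)
    cause = np.asarray(cause, dtype=int)
    if not np.all(np.isin(cause, (0, 1, 2))):
        raise ValueError("cause labels must be 0 (censored), 1 or 2")
    if (cause > 0).sum() == 0:
        raise ValueError("need at least one event")
    n_total = len(times)

    u, inv = np.unique(times, return_inverse=True)
    d1 = np.bincount(inv, weights=(cause == 1)).astype(int)
    d2 = np.bincount(inv, weights=(cause == 2)).astype(int)
    call = np.bincount(inv).astype(int)
    n_at_risk = n_total - np.concatenate(([0], np.cumsum(call)[:-1]))

    d = d1 + d2
    keep = d > 0
    tt, n_i = u[keep], n_at_risk[keep]
    d1, d2, d_i = d1[keep], d2[keep], d[keep]

    surv_factor = 1.0 - d_i / n_i
    s = np.cumprod(surv_factor)                 # all-cause KM at death times
    s_prev = np.concatenate(([1.0], s[:-1]))    # KM just before each time

    curves = []
    for dk in (d1, d2):
        if dk.sum() == 0:
            logger.warning("no events of one cause; its incidence curve is identically 0")
        inc = s_prev * dk / n_i
        f = np.cumsum(inc)

        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(n_i > d_i, d_i / (n_i * (n_i - d_i)), 0.0)
        b = s_prev * dk / n_i**2
        c2 = s_prev**2 * ((n_i - dk) / n_i) * dk / n_i**2
        ca, caf, caf2 = np.cumsum(a), np.cumsum(a * f), np.cumsum(a * f * f)
        cb, cbf, cc2 = np.cumsum(b), np.cumsum(b * f), np.cumsum(c2)
        var = (f * f * ca - 2 * f * caf + caf2) + cc2 - 2 * (f * cb - cbf)
        var = np.maximum(var, 0.0)

        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta_se = se / ((1.0 - f) * np.abs(np.log1p(-f)))
            lo = 1.0 - (1.0 - f) ** np.exp(-Z95 * theta_se)
            hi = 1.0 - (1.0 - f) ** np.exp(Z95 * theta_se)
        curves.append(StepSurvival(tt, f, lo, hi, n_i, dk, kind="incidence"))
    return curves[0], curves[1]
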