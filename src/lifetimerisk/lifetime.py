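"""Five-way comparison of lifetime-risk-of-death estimators.

Three estimators use cause-of-death labels — the raw proportion of deaths
attributed to the cancer, 1 - MFS at its plateau, and the cause-specific
cumulative incidence limit — and are biased downward when registries
under-report deaths from the cancer.  Two do not — 1 - relative survival at
its plateau, and 1 - exp(-AUC) from the fitted excess hazard — and are
therefore robust to misclassified causes of death.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .cohort import Cohort
from .ear import EarTable, TrigamFit, default_breaks, fit_trigam, lifetime_risk_from_auc, tabulate_ear
from .estimators import cif_fit, code_events, km_fit
from .lifetables import LifeTable
from .relsurv import expected_survival, relative_survival, sim_expected

DEFAULT_GRID = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
PLATEAU_TOL = 0.005


def raw_proportion(o_cancer: int, o_other: int, n_alive_projected: int = 0) -> float:
    """Proportion of deaths due to the cancer, optionally projecting survivors.

    With ``n_alive_projected`` those still alive are assumed to eventually
    die of other causes, deflating the proportion toward its lifetime value.
    """
    if min(o_cancer, o_other, n_alive_projected) < 0:
        raise ValueError("counts must be nonnegative")
    denom = o_cancer + o_other + n_alive_projected
    if denom == 0:
        raise ValueError("no deaths: proportion undefined")
    return o_cancer / denom


@dataclass
class LifetimeReport:
    """The five lifetime-risk estimates plus the supporting curves."""

    raw_prop: float
    raw_prop_projected: float
    one_minus_mfs: tuple        # (value, lo, hi) at plateau_time_mfs
    cif_limit: tuple            # (value, lo, hi) at plateau_time_mfs
    cif_plateau_reached: bool
    one_minus_rs: tuple         # (value, lo, hi) at plateau_time
    ear_based: float            # 1 - exp(-fitted AUC)
    plateau_time: float
    plateau_time_mfs: float
    grid: tuple
    table2: pd.DataFrame
    ear_table: EarTable
    trigam_fit: TrigamFit
    uses_cod: dict = field(default_factory=lambda: {
        "raw_prop": True, "raw_prop_projected": True, "one_minus_mfs": True,
        "cif_limit": True, "one_minus_rs": False, "ear_based": False,
    })
    provenance: dict = field(default_factory=dict)

    def estimates(self) -> dict:
        return {
            "raw_prop": self.raw_prop,
            "raw_prop_projected": self.raw_prop_projected,
            "one_minus_mfs": self.one_minus_mfs[0],
            "cif_limit": self.cif_limit[0],
            "one_minus_rs": self.one_minus_rs[0],
            "ear_based": self.ear_based,
        }

    def to_json(self, path=None) -> str:
        d = {
            "estimates": self.estimates(),
            "one_minus_mfs_ci": list(self.one_minus_mfs[1:]),
            "cif_limit_ci": list(self.cif_limit[1:]),
            "one_minus_rs_ci": list(self.one_minus_rs[1:]),
            "cif_plateau_reached": self.cif_plateau_reached,
            "plateau_time": self.plateau_time,
            "plateau_time_mfs": self.plateau_time_mfs,
            "trigam": {k: getattr(self.trigam_fit.params, k)
                       for k in ("A", "k", "theta", "H", "p_c", "w")},
            "auc": self.trigam_fit.auc,
            "uses_cod": self.uses_cod,
            "provenance": self.provenance,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compare_estimators(cohort: Cohort, table: LifeTable, *, seed: int = 0,
                       k_matched: int = 3, plateau_time: float = 25.0,
                       plateau_time_mfs: float = 35.0, grid=DEFAULT_GRID,
                       breaks=None, fix_triangle: bool = False,
                       n_alive_projected: int | None = None) -> LifetimeReport:
    """Run all five estimators end to end and assemble the comparison report.

    ``plateau_time`` (default 25 y) is where 1 - RS is read off;
    ``plateau_time_mfs`` (default 35 y) is where 1 - MFS and the cumulative
    incidence limit are read off.  Both are read-offs at fixed configurable
    times rather than automated plateau detection.  ``n_alive_projected``
    defaults to all currently alive cases (projected to other-cause deaths).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    grid = tuple(float(g) for g in grid)
    counts = cohort.counts()
    if counts["dead_cancer"] + counts["dead_other"] == 0:
        raise ValueError("cohort has no deaths; estimators undefined")
    if n_alive_projected is None:
        n_alive_projected = counts["alive"]

    raw = raw_proportion(counts["dead_cancer"], counts["dead_other"])
    raw_proj = raw_proportion(counts["dead_cancer"], counts["dead_other"], n_alive_projected)

    # stage: nonparametric curves
    os_curve = km_fit(*code_events(cohort, "OS"))
    mfs_curve = km_fit(*code_events(cohort, "MFS"))
    status = cohort.df["status"]
    cause = np.where(status == "dead_cancer", 1, np.where(status == "dead_other", 2, 0))
    cif_cancer, cif_other = cif_fit(cohort.df["futime"].to_numpy(), cause)

    # stage: relative survival
    exp_cohort = sim_expected(cohort, table, k=k_matched, seed=seed)
    exp_curve = expected_survival(exp_cohort)
    rs_grid = tuple(sorted(set(grid) | {plateau_time}))
    rs = relative_survival(os_curve, exp_curve, rs_grid)

    # stage: excess absolute risk and trigam fit
    breaks = default_breaks(max(42.0, float(cohort.df["futime"].max()))) \
        if breaks is None else np.asarray(breaks, dtype=float)
    ear = tabulate_ear(cohort, table, breaks)
    fit = fit_trigam(ear, fix_triangle=fix_triangle, seed=seed)

    mfs_at = mfs_curve.eval_at(plateau_time_mfs).iloc[0]
    one_minus_mfs = (1.0 - mfs_at["value"], 1.0 - mfs_at["hi"], 1.0 - mfs_at["lo"])
    cif_at = cif_cancer.eval_at(plateau_time_mfs).iloc[0]
    cif_limit = (cif_at["value"], cif_at["lo"], cif_at["hi"])
    cif_tail = cif_cancer.eval_at(list(grid[-2:]))["value"].to_numpy()
    plateau_reached = bool(abs(cif_tail[-1] - cif_tail[0]) < PLATEAU_TOL)
    rs_at = rs.eval_at(plateau_time).iloc[0]
    one_minus_rs = (1.0 - rs_at["value"], 1.0 - rs_at["hi"], 1.0 - rs_at["lo"])

    rows = []
    for name, curve in (("OS", os_curve), ("MFS", mfs_curve),
                        ("CIF_other", cif_other), ("CIF_cancer", cif_cancer)):
        ev = curve.eval_at(grid)
        for _, r in ev.iterrows():
            rows.append((r["time"], name, r["value"], r["lo"], r["hi"]))
    for _, r in rs.eval_at([g for g in grid]).iterrows():
        rows.append((r["time"], "RS", r["value"], r["lo"], r["hi"]))
    table2 = pd.DataFrame(rows, columns=["year", "metric", "estimate", "lo", "hi"])

    provenance = {
        "seed": seed, "k_matched": k_matched, "n_cases": len(cohort),
        "breaks": list(np.asarray(breaks, dtype=float)),
        "version": _pkg_version, "fix_triangle": fix_triangle,
    }
    return LifetimeReport(
        raw_prop=raw, raw_prop_projected=raw_proj,
        one_minus_mfs=one_minus_mfs, cif_limit=cif_limit,
        cif_plateau_reached=plateau_reached, one_minus_rs=one_minus_rs,
        ear_based=lifetime_risk_from_auc(fit.auc),
        plateau_time=plateau_time, plateau_time_mfs=plateau_time_mfs,
        grid=grid, table2=table2, ear_table=ear, trigam_fit=fit,
        provenance=provenance,
    )
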