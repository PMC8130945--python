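"""Case-listing data model, ICD-O-3 cohort selection, and delimited-text I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = ("alive", "dead_cancer", "dead_other")

#: melanoma morphology range and eye sites retained by the cohort filter
MORPH_RANGE = (8720, 8790)
UVEAL_SITES = ("C69.2", "C69.3", "C69.4")

HALF_MONTH_YEARS = 0.5 / 12.0

_COLUMNS = ["id", "sex", "age_dx", "year_dx", "futime", "status", "morph", "site"]


@dataclass(frozen=True)
class CaseRecord:
    """One registry case.

    ``futime`` is years from diagnosis to death or censoring; ``status`` is
    one of ``alive`` (right-censored), ``dead_cancer`` (cause of death is the
    cancer of interest) or ``dead_other``.  ``morph`` is the ICD-O-3
    morphology code, ``site`` the ICD-O-3 topography string (e.g. "C69.3").
    """

    id: str
    sex: str
    age_dx: float
    year_dx: float
    futime: float
    status: str
    morph: int = 0
    site: str = ""

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.futime <= 0:
            raise ValueError("futime must be positive")
        if self.age_dx < 0:
            raise ValueError("age at diagnosis must be nonnegative")


@dataclass
class Cohort:
    """Ordered collection of cases plus the administrative censoring year."""

    df: pd.DataFrame
    study_end: float = np.nan

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["id"].duplicated().any():
            raise ValueError("case ids must be unique")
        if len(self.df):
            if (self.df["futime"] <= 0).any():
                raise ValueError("all follow-up times must be positive")
            if (self.df["age_dx"] + self.df["futime"] > 125).any():
                raise ValueError("age at exit exceeds 125 years for some case")
            bad = ~self.df["status"].isin(STATUSES)
            if bad.any():
                raise ValueError(f"invalid status values: {self.df.loc[bad, 'status'].unique()}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cases(self):
        return [CaseRecord(**row) for row in self.df[_COLUMNS].to_dict("records")]

    @classmethod
    def from_records(cls, records, study_end=np.nan) -> "Cohort":
        df = pd.DataFrame([vars(r) if isinstance(r, CaseRecord) else r for r in records],
                          columns=_COLUMNS)
        return cls(df, study_end)

    def counts(self) -> dict:
        c = self.df["status"].value_counts()
        return {s: int(c.get(s, 0)) for s in STATUSES}


def filter_uveal_melanoma(cases) -> Cohort:
    """Retain melanoma morphologies (8720-8790) at uveal sites C69.2/.3/.4.

    Accepts a Cohort, DataFrame, or iterable of CaseRecord; preserves order
    and logs the retained/dropped counts.
    """
    if isinstance(cases, Cohort):
        df, study_end = cases.df, cases.study_end
    elif isinstance(cases, pd.DataFrame):
        df, study_end = cases, np.nan
    else:
        df, study_end = Cohort.from_records(cases).df, np.nan
    morph = pd.to_numeric(df["morph"])
    keep = (morph >= MORPH_RANGE[0]) & (morph <= MORPH_RANGE[1]) & df["site"].isin(UVEAL_SITES)
    logger.info("cohort filter: retained %d, dropped %d", int(keep.sum()), int((~keep).sum()))
    return Cohort(df[keep].reset_index(drop=True), study_end)


DEFAULT_MAPPING = {
    "id": "id", "sex": "sex", "age_dx": "age_dx", "year_dx": "year_dx",
    "srv_time_mon": "srv_time_mon", "status": "status", "morph": "morph", "site": "site",
}


def read_cases(path, mapping=None, sep=",", status_map=None, study_end=np.nan) -> Cohort:
    """Read a delimited case listing into a Cohort.

    ``mapping`` names the file's columns for each field; survival time may be
    given in months (``srv_time_mon`` key, divided by 12) or years (``futime``
    key).  Registries record whole months, so a survival time of zero is set
    to half a month (0.5/12 years) and flagged — zero-length follow-up breaks
    product-limit estimators.  Rows with missing status are dropped with a
    logged count; unparseable numeric rows are collected, logged, and skipped.
    """
    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    time_key = "srv_time_mon" if "srv_time_mon" in mapping else "futime"
    needed = ["id", "sex", "age_dx", "year_dx", time_key, "status", "morph", "site"]
    for key in needed:
        if key not in mapping:
            raise KeyError(f"column mapping is missing key {key!r}")
        if mapping[key] not in raw.columns:
            raise KeyError(f"mapped column {mapping[key]!r} (for {key!r}) not in file")

    df = pd.DataFrame({k: raw[mapping[k]] for k in needed})
    n0 = len(df)
    df = df[df["status"].notna() & (df["status"].astype(str).str.strip() != "")]
    if len(df) < n0:
        logger.warning("dropped %d rows with missing status", n0 - len(df))
    if status_map:
        df["status"] = df["status"].map(lambda s: status_map.get(s, s))

    numeric = ["age_dx", "year_dx", time_key, "morph"]
    conv = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = conv.isna().any(axis=1)
    if bad.any():
        for idx in df.index[bad]:
            logger.error("row %s: unparseable numeric field; skipped", idx)
    df = df[~bad]
    conv = conv[~bad]

    futime = conv[time_key] / 12.0 if time_key == "srv_time_mon" else conv[time_key]
    zero = futime <= 0
    if zero.any():
        logger.warning("%d rows with zero follow-up set to half a month", int(zero.sum()))
        futime = futime.where(~zero, HALF_MONTH_YEARS)

    out = pd.DataFrame({
        "id": df["id"].astype(str),
        "sex": df["sex"].astype(str),
        "age_dx": conv["age_dx"].astype(float),
        "year_dx": conv["year_dx"].astype(float),
        "futime": futime.astype(float),
        "status": df["status"].astype(str),
        "morph": conv["morph"].astype(int),
        "site": df["site"].astype(str),
    })
    return Cohort(out, study_end)


def write_cases(cohort: Cohort, path, sep=",", months=True) -> None:
    """Write a cohort in the package's own delimited dialect (round-trips)."""
    df = cohort.df.copy()
    if months:
        df["srv_time_mon"] = df.pop("futime") * 12.0
        cols = ["id", "sex", "age_dx", "year_dx", "srv_time_mon", "status", "morph", "site"]
    else:
        cols = _COLUMNS
    df[cols].to_csv(path, sep=sep, index=False, float_format="%.10g")


def split_by_age(cohort: Cohort, cut: float = 50.0):
    """Partition into (age_dx < cut, age_dx >= cut); the boundary goes old."""
    if cut <= 0:
        raise ValueError("cut must be positive")
    young = cohort.df["age_dx"] < cut
    return (Cohort(cohort.df[young].reset_index(drop=True), cohort.study_end),
            Cohort(cohort.df[~young].reset_index(drop=True), cohort.study_end))
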