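"""Background mortality-rate surfaces (period life tables).

A :class:`LifeTable` stores the central death rate m(sex, age, year) on a grid
of single years of age and single calendar years.  Rates are interpreted as
constant hazards within each one-year Lexis cell, so survival over a duration
``d`` inside one cell is ``exp(-m * d)`` — this makes expected-death
integration exact and additive over Lexis splits.

Tables can be read from the Human Mortality Database period Mx_1x1 text
dialect or synthesised from a Gompertz-Makeham law for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

RATE_CAP = 10.0  # hazards above this are not biologically meaningful

_SEXES = ("female", "male")


def _sex_index(sex: str) -> int:
    s = str(sex).strip().lower()
    if s in ("f", "female"):
        return 0
    if s in ("m", "male"):
        return 1
    raise ValueError(f"unknown sex label {sex!r}; expected 'female'/'f' or 'male'/'m'")


@dataclass
class LifeTable:
    """Mortality hazard per person-year on a (sex, age, year) grid.

    ``rates`` has shape ``(2, age_max - age_min + 1, year_max - year_min + 1)``
    with axis 0 ordered (female, male).  The top age is an open interval
    ("110+" in HMD files): lookups above ``age_max`` clamp to it, and lookups
    outside the calendar-year range clamp to the nearest boundary year so that
    long follow-ups past the last table year remain computable.
    """

    age_min: int
    age_max: int
    year_min: int
    year_max: int
    rates: np.ndarray
    sex_labels: tuple = field(default=_SEXES)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        expected = (2, self.age_max - self.age_min + 1, self.year_max - self.year_min + 1)
        if self.rates.shape != expected:
            raise ValueError(f"rates shape {self.rates.shape} != expected {expected}")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("all rates must be finite and nonnegative")

    def get_rate(self, sex, age, year):
        """Hazard for (sex, floor(age), floor(year)), clamped to the grid.

        ``age`` and ``year`` may be scalars or arrays (broadcast together).
        Ages above ``age_max`` clamp to the open top age group; calendar
        years outside the table clamp to the nearest boundary year.
        Negative ages raise.
        """
        si = _sex_index(sex)
        age = np.asarray(age, dtype=float)
        year = np.asarray(year, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be nonnegative")
        ai = np.clip(np.floor(age).astype(int) - self.age_min, 0, self.rates.shape[1] - 1)
        yi = np.clip(np.floor(year).astype(int) - self.year_min, 0, self.rates.shape[2] - 1)
        out = self.rates[si, ai, yi]
        return out if out.shape else float(out)


def make_synthetic_lifetable(
    makeham_a: float = 5e-4,
    gompertz_b: float = 3e-5,
    gompertz_c: float = 0.09,
    years: tuple = (1975, 2020),
    age_max: int = 110,
    secular_decline: float = 0.0,
    male_female_ratio: float = 1.0,
) -> LifeTable:
    """Gompertz-Makeham life table, optionally with secular mortality decline.

    rate(sex, age, year) = (a + b * exp(c * age)) * (1 - decline)^(year - year_min),
    scaled by ``male_female_ratio`` for males.  Rates above 10 per person-year
    are capped with a logged warning.
    """
    if makeham_a < 0 or gompertz_b < 0:
        raise ValueError("makeham_a and gompertz_b must be nonnegative")
    if gompertz_c <= 0:
        raise ValueError("gompertz_c must be positive")
    if not 0 <= secular_decline < 1:
        raise ValueError("secular_decline must be in [0, 1)")
    year_min, year_max = int(years[0]), int(years[1])
    ages = np.arange(0, age_max + 1, dtype=float)
    yrs = np.arange(year_min, year_max + 1, dtype=float)
    base = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    decline = (1.0 - secular_decline) ** (yrs - year_min)
    female = base[:, None] * decline[None, :]
    male = female * male_female_ratio
    rates = np.stack([female, male])
    if np.any(rates > RATE_CAP):
        logger.warning(
            "synthetic life table produced rates above %.0f per person-year; capping", RATE_CAP
        )
        rates = np.minimum(rates, RATE_CAP)
    return LifeTable(0, age_max, year_min, year_max, rates)


# ---------------------------------------------------------------------------
# HMD Mx_1x1 dialect

def read_hmd_mx(path) -> LifeTable:
    """Read a period Mx_1x1 file (Year Age Female Male Total, '.' = missing).

    Header lines before the column header are skipped.  Age "110+" maps to
    110.  Missing rates are filled by carrying the last finite rate at lower
    age forward within the same sex and year (0 if none).
    """
    years, ages, fem, mal = [], [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        toks = line.split()
        if toks and toks[0].lower() == "year":
            start = i + 1
            break
    if start is None:
        # no column header: find first line that parses as data
        start = 0
        while start < len(lines) and not _looks_like_row(lines[start]):
            start += 1
    for lineno, line in enumerate(lines[start:], start + 1):
        toks = line.split()
        if not toks:
            continue
        if len(toks) != 5:
            raise ValueError(f"line {lineno}: expected 5 columns, got {len(toks)}")
        years.append(int(toks[0]))
        ages.append(110 if toks[1].endswith("+") else int(toks[1]))
        fem.append(np.nan if toks[2] == "." else float(toks[2]))
        mal.append(np.nan if toks[3] == "." else float(toks[3]))
    if not years:
        raise ValueError("no data rows found")
    years = np.array(years)
    ages = np.array(ages)
    year_min, year_max = int(years.min()), int(years.max())
    age_min, age_max = int(ages.min()), int(ages.max())
    n_age = age_max - age_min + 1
    n_year = year_max - year_min + 1
    rates = np.full((2, n_age, n_year), np.nan)
    for yr in range(year_min, year_max + 1):
        sel = years == yr
        if np.any(np.diff(ages[sel]) <= 0):
            raise ValueError(f"non-monotone ages within year {yr}")
    rates[0, ages - age_min, years - year_min] = fem
    rates[1, ages - age_min, years - year_min] = mal
    # carry last finite rate at lower age forward; 0 if none below
    for s in range(2):
        for j in range(n_year):
            col = rates[s, :, j]
            last = 0.0
            for i in range(n_age):
                if np.isfinite(col[i]):
                    last = col[i]
                else:
                    col[i] = last
    return LifeTable(age_min, age_max, year_min, year_max, rates)


def _looks_like_row(line: str) -> bool:
    toks = line.split()
    if len(toks) != 5:
        return False
    try:
        int(toks[0])
        return True
    except ValueError:
        return False


def write_hmd_mx(table: LifeTable, path) -> None:
    """Write a LifeTable in the Mx_1x1 dialect (Total = mean of sexes)."""
    with open(path, "w") as fh:
        fh.write("Synthetic period death rates (Mx_1x1 dialect)\n\n")
        fh.write("  Year          Age             Female            Male           Total\n")
        for j, yr in enumerate(range(table.year_min, table.year_max + 1)):
            for i, age in enumerate(range(table.age_min, table.age_max + 1)):
                label = f"{age}+" if age == table.age_max == 110 else str(age)
                f = table.rates[0, i, j]
                m = table.rates[1, i, j]
                fh.write(f"  {yr}   {label:>10}   {f:.6f}   {m:.6f}   {(f + m) / 2:.6f}\n")
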