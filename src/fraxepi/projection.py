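"""Demographic projection of fracture counts.

Applies age/sex-specific incidence, assumed stable over calendar time, to
population projections to estimate expected national annual fracture
counts and their percentage change relative to a base year.  Expected
counts are exact sums of rate x population over strata; they are kept
unrounded internally (reports round to integers) and percent changes are
computed from the unrounded totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .incidence import round_half_away

PROJECTION_COLUMNS = ("sex", "age_lo", "age_hi", "year", "population")


def read_projection_csv(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter)
    missing = [c for c in PROJECTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"projection table missing column {missing[0]!r}")
    if (frame["population"] < 0).any():
        raise ValueError("projected populations must be non-negative")
    return frame


def expected_fractures(
    rates: pd.DataFrame,
    pop: pd.DataFrame,
    year: int,
    sex: str,
    min_age: int = 50,
) -> float:
    """Expected annual fracture count: sum of rate/100,000 x population.

    Every populated band at or above ``min_age`` must have a matching rate
    row (same sex and band lower edge); a mismatch is a hard error listing
    the missing bands.
    """
    sub = pop[(pop["year"] == year) & (pop["sex"] == sex)
              & (pop["age_lo"] >= min_age)]
    rate_rows = rates[rates["sex"] == sex].set_index("age_lo")["rate"]
    missing = sorted(set(sub["age_lo"]) - set(rate_rows.index))
    if missing:
        raise ValueError(
            f"no incidence rate for {sex} bands starting at {missing}"
        )
    total = 0.0
    for row in sub.itertuples(index=False):
        total += float(rate_rows.loc[row.age_lo]) / 100_000.0 * float(row.population)
    return total


@dataclass
class ProjectionResult:
    """Expected fracture counts per (year, sex) under stable rates."""

    by_year_sex: pd.DataFrame  # columns: year, sex, expected
    base_year: int

    @property
    def totals(self) -> pd.Series:
        return self.by_year_sex.groupby("year")["expected"].sum()

    def percent_change(self, year: int, sex: str | None = None) -> float:
        """(count_year / count_base - 1) x 100, from unrounded counts."""
        if sex is None:
            num = float(self.totals.loc[year])
            den = float(self.totals.loc[self.base_year])
        else:
            frame = self.by_year_sex
            num = float(frame[(frame["year"] == year)
                              & (frame["sex"] == sex)]["expected"].sum())
            den = float(frame[(frame["year"] == self.base_year)
                              & (frame["sex"] == sex)]["expected"].sum())
        if den == 0:
            raise ValueError("base-year expected count is zero")
        return (num / den - 1.0) * 100.0

    def report(self) -> pd.DataFrame:
        """Printable table: integer counts per year/sex, totals and the
        percent-change row computed from unrounded totals."""
        wide = self.by_year_sex.pivot(index="sex", columns="year",
                                      values="expected")
        out = wide.map(round_half_away)
        out.loc["total"] = wide.sum(axis=0).map(round_half_away)
        out.loc["increase_pct"] = [
            round_half_away(self.percent_change(int(y)))
            if int(y) != self.base_year else math.nan
            for y in wide.columns
        ]
        return out


def project_series(
    rates: pd.DataFrame,
    pop: pd.DataFrame,
    years: Sequence[int],
    base_year: int,
    sexes: Sequence[str] = ("male", "female"),
    min_age: int = 50,
) -> ProjectionResult:
    """Expected counts for each year and sex, anchored at ``base_year``."""
    if base_year not in years:
        raise ValueError("base year must be among the projected years")
    rows = [
        {"year": int(y), "sex": sex,
         "expected": expected_fractures(rates, pop, int(y), sex, min_age)}
        for y in years for sex in sexes
    ]
    return ProjectionResult(pd.DataFrame(rows), base_year=int(base_year))
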