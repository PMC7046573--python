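"""Age/sex-specific incidence with exact Poisson intervals and the
prospective-capture uplift.

Rates are events per 100,000 person-years.  Interval estimates are exact
(Garwood) Poisson limits built from gamma quantiles: for an observed count
``k`` over person-years ``PY`` at level ``1 - alpha`` the event-scale
limits are

    lower = Gamma(k).ppf(alpha/2)          (0 when k = 0)
    upper = Gamma(k + 1).ppf(1 - alpha/2)

divided by ``PY`` and scaled to 100,000.  The gamma formulation accepts
fractional counts, which arise after ascertainment adjustment: a registry
that only sees the fraction of cases reaching hospital sources is uplifted
by the factor (retrospective annual count + additional prospectively found
cases) / retrospective annual count, and the uplifted counts are carried
as fractions rather than rounded.

Reported tables round rates half away from zero to integers and ratios to
one decimal, matching the usual presentation of registry incidence tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import AgeBand, find_band, nests_within
from .registry import FractureRecord, PopulationTable

PER = 100_000.0

#: Column contract for incidence tables.
INCIDENCE_COLUMNS = (
    "sex", "age_lo", "age_hi", "site", "events", "person_years",
    "rate", "ci_low", "ci_high", "adjusted",
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class StratumCount:
    """Events and person-years for one (sex, age band, site) cell.

    ``events`` may be fractional after capture adjustment.
    """

    sex: str
    band: AgeBand
    site: str
    events: float
    person_years: float

    def __post_init__(self) -> None:
        if self.events < 0:
            raise ValueError("events must be non-negative")


def crude_rate(events: float, person_years: float) -> float:
    """Events per 100,000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    return events / person_years * PER


def poisson_ci_events(events: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) limits for a Poisson mean, on the event scale."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if events < 0:
        raise ValueError("events must be non-negative")
    alpha = 1.0 - level
    lower = 0.0 if events == 0 else float(stats.gamma.ppf(alpha / 2.0, events))
    upper = float(stats.gamma.ppf(1.0 - alpha / 2.0, events + 1.0))
    return lower, upper


def exact_poisson_ci(
    events: float, person_years: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact Poisson interval for the rate, per 100,000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    lo, hi = poisson_ci_events(events, level)
    return lo / person_years * PER, hi / person_years * PER


@dataclass(frozen=True)
class CaptureAdjustment:
    """Multiplicative uplift for cases missed by hospital-only sources.

    Estimated from a prospective phase with additional primary-care
    ascertainment: if the retrospective phase found ``retro_annual_count``
    cases per year and the prospective phase found
    ``additional_prospective_count`` more, counts in the retrospective
    years are multiplied by (retro + additional) / retro.
    """

    sex: str
    retro_annual_count: float
    additional_prospective_count: float
    applies_to_years: frozenset[int] = field(default_factory=frozenset)

    @property
    def factor(self) -> float:
        return (
            self.retro_annual_count + self.additional_prospective_count
        ) / self.retro_annual_count

    @property
    def percent_uplift(self) -> int:
        """(factor - 1) x 100, rounded half away from zero."""
        return round_half_away((self.factor - 1.0) * 100.0)


def capture_adjustment_factor(
    retro_annual_count: float,
    additional_prospective_count: float,
    sex: str = "",
    applies_to_years: Iterable[int] = (),
) -> CaptureAdjustment:
    if retro_annual_count <= 0:
        raise ValueError("adjustment undefined for zero retrospective count")
    if additional_prospective_count < 0:
        raise ValueError("additional count must be non-negative")
    return CaptureAdjustment(
        sex=sex,
        retro_annual_count=retro_annual_count,
        additional_prospective_count=additional_prospective_count,
        applies_to_years=frozenset(int(y) for y in applies_to_years),
    )


def apply_adjustment(
    counts_by_year: Mapping[int, float], adj: CaptureAdjustment
) -> dict[int, float]:
    """Multiply counts in the adjustment years by the uplift factor.

    Fractional results are carried, not rounded; other years pass through.
    """
    missing = adj.applies_to_years - set(counts_by_year)
    if missing:
        raise ValueError(f"counts missing for adjustment years {sorted(missing)}")
    return {
        year: (count * adj.factor if year in adj.applies_to_years else float(count))
        for year, count in counts_by_year.items()
    }


def female_male_ratio(female_events: float, male_events: float) -> float | None:
    """Female/male event ratio; None (absent) when there are no male events.

    Reported tables print this to one decimal.
    """
    if male_events < 0 or female_events < 0:
        raise ValueError("event counts must be non-negative")
    if male_events == 0:
        return None
    return female_events / male_events


def incidence_table(
    strata: Iterable[StratumCount],
    level: float = 0.95,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Assemble an incidence table (one row per stratum) with exact CIs.

    Strata with zero person-years are not allowed; rate and interval are
    recomputed from events and person-years, never taken on trust.
    """
    rows = []
    for s in strata:
        rate = crude_rate(s.events, s.person_years)
        lo, hi = exact_poisson_ci(s.events, s.person_years, level)
        rows.append({
            "sex": s.sex,
            "age_lo": s.band.lower,
            "age_hi": s.band.upper,
            "site": s.site,
            "events": float(s.events),
            "person_years": float(s.person_years),
            "rate": rate,
            "ci_low": lo,
            "ci_high": hi,
            "adjusted": adjusted,
        })
    return pd.DataFrame(rows, columns=list(INCIDENCE_COLUMNS))


def strata_from_records(
    records: Sequence[FractureRecord],
    pop: PopulationTable,
    bands: Sequence[AgeBand],
    site: str,
    years: Iterable[int],
    fallback_nearest: bool = False,
) -> list[StratumCount]:
    """Cross-tabulate records into per-(sex, band) strata for one site."""
    years = [int(y) for y in years]
    counts: dict[tuple[str, AgeBand], int] = {}
    for rec in records:
        if rec.site_group != site:
            continue
        band = find_band(bands, rec.age_years)
        key = (rec.sex, band)
        counts[key] = counts.get(key, 0) + 1
    strata = []
    for sex in ("men", "women"):
        sex_key = "male" if sex == "men" else "female"
        for band in bands:
            events = counts.get((sex_key, band), 0)
            py = pop.person_years(sex_key, band, years,
                                  fallback_nearest=fallback_nearest)
            strata.append(StratumCount(sex_key, band, site, events, py))
    return strata


def aggregate_bands(
    table: pd.DataFrame, scheme: Sequence[AgeBand], level: float = 0.95
) -> pd.DataFrame:
    """Re-tabulate an incidence table on a coarser band scheme.

    Events and person-years are summed within each coarse band and the rate
    and interval recomputed from the sums.  The coarse scheme must be a
    union of the fine bands.
    """
    fine = [
        AgeBand(int(lo), hi if math.isfinite(hi) else math.inf)
        for lo, hi in table[["age_lo", "age_hi"]].drop_duplicates().itertuples(index=False)
    ]
    if not nests_within(scheme, fine):
        raise ValueError("coarser scheme does not nest the table's bands")
    rows = []
    for (sex, site), group in table.groupby(["sex", "site"], sort=False):
        adjusted = bool(group["adjusted"].any())
        for band in scheme:
            mask = (group["age_lo"] >= band.lower) & (
                group["age_lo"] < band.upper
            )
            sub = group[mask]
            if sub.empty:
                continue
            events = float(sub["events"].sum())
            py = float(sub["person_years"].sum())
            rate = crude_rate(events, py)
            lo, hi = exact_poisson_ci(events, py, level)
            rows.append({
                "sex": sex, "age_lo": band.lower, "age_hi": band.upper,
                "site": site, "events": events, "person_years": py,
                "rate": rate, "ci_low": lo, "ci_high": hi,
                "adjusted": adjusted,
            })
    return pd.DataFrame(rows, columns=list(INCIDENCE_COLUMNS))


@dataclass(frozen=True)
class CarePathway:
    """Hospital care-pathway proportions for an index-fracture cohort."""

    n_cases: int
    n_refused: int
    n_admitted: int
    n_surgical: int

    @property
    def pct_refused(self) -> int:
        return round_half_away(100.0 * self.n_refused / self.n_cases)

    @property
    def pct_surgical_among_admitted(self) -> int | None:
        if self.n_admitted == 0:
            return None
        return round_half_away(100.0 * self.n_surgical / self.n_admitted)

    @property
    def pct_untreated_or_conservative(self) -> int:
        return round_half_away(
            100.0 * (self.n_cases - self.n_surgical) / self.n_cases
        )


def care_pathway_summary(records: Sequence[FractureRecord]) -> CarePathway:
    """Refusal / surgery proportions among hip (or any) fracture cases."""
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    refused = sum(1 for r in records if r.admitted == "refused")
    admitted = sum(1 for r in records if r.admitted == "admitted")
    surgical = sum(
        1 for r in records if r.admitted == "admitted" and r.surgical
    )
    return CarePathway(n, refused, admitted, surgical)


def format_report(table: pd.DataFrame) -> pd.DataFrame:
    """Printable view: rates/CIs rounded half away from zero to integers."""
    out = table.copy()
    for col in ("rate", "ci_low", "ci_high"):
        out[col] = out[col].map(
            lambda x: round_half_away(x) if np.isfinite(x) else x
        )
    return out
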