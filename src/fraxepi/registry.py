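"""Ingest, validation, filtering and deduplication of fracture case records.

A registry file is UTF-8 delimited text with a header row.  One row is one
ascertained fracture case: pseudonymous person id, sex, age at fracture in
completed years, calendar year of the event, ICD-10 site code, admission
status (admitted / refused / not_presented), whether the case was treated
surgically, whether the fracture was pathological (metastatic cancer or
myeloma), whether the person was a permanent resident of the catchment
area, and whether the fracture was confirmed radiographically.

Case definitions follow the ICD-10 site sets conventional in osteoporotic
fracture surveillance: proximal femur S72.0-S72.2 ("hip"), distal forearm
S52.5-S52.6, proximal humerus S42.2.  Eligibility for incidence estimation
is: configured site, age >= 40, permanent resident, non-pathological,
radiographically confirmed (clinically verified hip cases may be accepted
when prospective home-visit ascertainment is in use), event year inside the
study window.  High-energy trauma is *not* an exclusion.  Re-admissions for
the same fracture site within the observation window are collapsed to the
first admission.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .bands import AgeBand

# ICD-10 code sets by site group.
SITE_CODES: dict[str, frozenset[str]] = {
    "hip": frozenset({"S72.0", "S72.1", "S72.2"}),
    "forearm": frozenset({"S52.5", "S52.6"}),
    "humerus": frozenset({"S42.2"}),
}

ADMISSION_STATES = ("admitted", "refused", "not_presented")

REQUIRED_COLUMNS = (
    "person_id",
    "sex",
    "age",
    "year",
    "icd10",
    "admitted",
    "surgical",
    "pathological",
    "resident",
    "radiograph",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}

_SEX_ALIASES = {
    "m": "male", "male": "male", "men": "male",
    "f": "female", "female": "female", "women": "female",
}


@dataclass(frozen=True)
class FractureRecord:
    """One ascertained fracture case with its eligibility attributes."""

    person_id: str
    sex: str  # "male" | "female"
    age_years: int
    event_year: int
    site: str  # ICD-10 code, e.g. "S72.0"
    admitted: str  # "admitted" | "refused" | "not_presented"
    surgical: bool
    pathological: bool
    resident: bool
    radiograph_confirmed: bool

    @property
    def site_group(self) -> str | None:
        return site_group(self.site)


def site_group(icd10: str) -> str | None:
    """Map an ICD-10 code to its site group, or None if unconfigured."""
    code = icd10.strip().upper().replace(" ", "")
    for group, codes in SITE_CODES.items():
        if code in codes:
            return group
    return None


@dataclass
class Rejection:
    row_number: int  # 1-based data-row index
    reason: str
    raw: Mapping[str, str] | FractureRecord


@dataclass
class IngestResult:
    """Records plus a full audit trail: rows in = records + rejections."""

    records: list[FractureRecord]
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.records) + len(self.rejections)


def _parse_bool(value: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"unparsable boolean {value!r} in column {column!r}")


def _parse_row(row: Mapping[str, str]) -> FractureRecord:
    sex_raw = str(row["sex"]).strip().lower()
    if sex_raw not in _SEX_ALIASES:
        raise ValueError(f"unparsable sex {row['sex']!r}")
    try:
        age = int(str(row["age"]).strip())
    except ValueError:
        raise ValueError(f"unparsable age {row['age']!r}") from None
    if age < 0:
        raise ValueError(f"negative age {age}")
    try:
        year = int(str(row["year"]).strip())
    except ValueError:
        raise ValueError(f"unparsable year {row['year']!r}") from None
    admitted = str(row["admitted"]).strip().lower()
    if admitted not in ADMISSION_STATES:
        raise ValueError(f"unparsable admission status {row['admitted']!r}")
    return FractureRecord(
        person_id=str(row["person_id"]).strip(),
        sex=_SEX_ALIASES[sex_raw],
        age_years=age,
        event_year=year,
        site=str(row["icd10"]).strip().upper().replace(" ", ""),
        admitted=admitted,
        surgical=_parse_bool(row["surgical"], "surgical"),
        pathological=_parse_bool(row["pathological"], "pathological"),
        resident=_parse_bool(row["resident"], "resident"),
        radiograph_confirmed=_parse_bool(row["radiograph"], "radiograph"),
    )


def read_registry(path: str | Path, delimiter: str = ",") -> IngestResult:
    """Read a registry file; every row becomes a record or a rejection.

    Raises ``ValueError`` naming the column if a required column is absent
    from the header.  Row order is preserved in ``records``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ValueError(f"registry file missing required column {col!r}")
        result = IngestResult(records=[])
        for i, row in enumerate(reader, start=1):
            try:
                result.records.append(_parse_row(row))
            except ValueError as exc:
                result.rejections.append(Rejection(i, str(exc), dict(row)))
    return result


def records_from_frame(frame: pd.DataFrame) -> IngestResult:
    """Build records from an in-memory DataFrame with the registry columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"registry frame missing required column {missing[0]!r}")
    result = IngestResult(records=[])
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            result.records.append(_parse_row(row))
        except ValueError as exc:
            result.rejections.append(Rejection(i, str(exc), row))
    return result


def filter_eligible(
    records: Iterable[FractureRecord],
    site_set: Iterable[str],
    min_age: int = 40,
    study_window: tuple[int, int] = (2015, 2017),
    require_radiograph: bool = True,
    accept_clinical_hip: bool = False,
) -> tuple[list[FractureRecord], list[Rejection]]:
    """Apply the eligibility rules; returns (retained, excluded-with-reason).

    ``site_set`` is a set of ICD-10 codes (site-group names such as "hip"
    are also accepted and expanded).  ``accept_clinical_hip`` retains hip
    cases verified clinically only, as under prospective home-visit
    ascertainment.  Trauma energy is never an exclusion criterion.
    """
    codes: set[str] = set()
    for item in site_set:
        if item in SITE_CODES:
            codes |= SITE_CODES[item]
        else:
            codes.add(item.strip().upper().replace(" ", ""))
    if not codes:
        raise ValueError("empty site set")
    lo, hi = study_window

    retained: list[FractureRecord] = []
    excluded: list[Rejection] = []
    for i, rec in enumerate(records, start=1):
        reason = None
        if rec.site not in codes:
            reason = f"site {rec.site} not in site set"
        elif rec.age_years < min_age:
            reason = f"age {rec.age_years} below {min_age}"
        elif not (lo <= rec.event_year <= hi):
            reason = f"year {rec.event_year} outside window {lo}-{hi}"
        elif not rec.resident:
            reason = "non-resident"
        elif rec.pathological:
            reason = "pathological fracture"
        elif require_radiograph and not rec.radiograph_confirmed:
            if not (accept_clinical_hip and rec.site_group == "hip"):
                reason = "not radiographically confirmed"
        if reason is None:
            retained.append(rec)
        else:
            excluded.append(Rejection(i, reason, rec))
    return retained, excluded


def deduplicate(records: Sequence[FractureRecord]) -> list[FractureRecord]:
    """Collapse re-admissions: one record per (person, site group), keeping
    the earliest event year; ties on year keep the first-seen row.

    Laterality is not recorded, so left/right fractures of the same site
    within the window collapse to one.
    """
    best: dict[tuple[str, str | None], tuple[int, int]] = {}
    for idx, rec in enumerate(records):
        key = (rec.person_id, rec.site_group)
        if key not in best:
            best[key] = (rec.event_year, idx)
        else:
            year, _ = best[key]
            if rec.event_year < year:
                best[key] = (rec.event_year, idx)
    keep = sorted(idx for _, idx in best.values())
    return [records[i] for i in keep]


class PopulationTable:
    """Population denominators keyed by (sex, age band, calendar year).

    Backed by a DataFrame with columns sex, age_lo, age_hi, year, count.
    ``age_hi`` is the exclusive upper band edge (NaN / blank = open band).
    Person-years for a stratum over a period are the annual counts summed,
    so a table printed as "2015-2017 combined" equals three annual columns
    added together.
    """

    COLUMNS = ("sex", "age_lo", "age_hi", "year", "count")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"population table missing column {missing[0]!r}")
        if (frame["count"] < 0).any():
            raise ValueError("population counts must be non-negative")
        self._frame = frame.reset_index(drop=True)
        self._cells: dict[tuple[str, int, int], float] = {}
        for row in self._frame.itertuples(index=False):
            hi = row.age_hi
            hi_key = -1 if (hi is None or (isinstance(hi, float) and math.isnan(hi)) or math.isinf(hi)) else int(hi)
            key = (str(row.sex), int(row.age_lo), hi_key, int(row.year))
            self._cells[key] = self._cells.get(key, 0.0) + float(row.count)

    @classmethod
    def read_csv(cls, path: str | Path, delimiter: str = ",") -> "PopulationTable":
        return cls(pd.read_csv(path, sep=delimiter))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def years(self) -> list[int]:
        return sorted(int(y) for y in self._frame["year"].unique())

    def _cell(self, sex: str, band: AgeBand, year: int,
              fallback_nearest: bool) -> float:
        hi_key = -1 if band.is_open else int(band.upper)
        key = (sex, band.lower, hi_key, year)
        if key in self._cells:
            return self._cells[key]
        # aggregate finer cells that exactly tile the requested band
        parts = sorted(
            (lo, hi, self._cells[(s, lo, hi, y)])
            for (s, lo, hi, y) in self._cells
            if s == sex and y == year and lo >= band.lower
            and (band.is_open or (hi != -1 and hi <= band.upper))
        )
        if parts:
            covered = parts[0][0] == band.lower
            for (lo_a, hi_a, _), (lo_b, _, _) in zip(parts, parts[1:]):
                covered &= hi_a == lo_b
            tail_open = parts[-1][1] == -1
            covered &= (band.is_open and tail_open) or (
                not band.is_open and parts[-1][1] == band.upper
            )
            if covered:
                return sum(v for *_, v in parts)
        if fallback_nearest:
            candidates = [
                y for (s, lo, hi, y) in self._cells
                if s == sex and lo == band.lower and hi == hi_key
            ]
            if candidates:
                nearest = min(candidates, key=lambda y: (abs(y - year), y))
                return self._cells[(sex, band.lower, hi_key, nearest)]
        raise KeyError(
            f"no population cell for sex={sex}, band={band.label}, year={year}"
        )

    def person_years(
        self,
        sex: str,
        band: AgeBand,
        years: Iterable[int],
        fallback_nearest: bool = False,
    ) -> float:
        """Sum of annual populations for the stratum over ``years``.

        Missing cells raise ``KeyError`` naming the cell unless
        ``fallback_nearest`` replicates the nearest available year.
        """
        return sum(
            self._cell(sex, band, int(y), fallback_nearest) for y in years
        )


def person_years(
    pop: PopulationTable,
    sex: str,
    band: AgeBand,
    years: Iterable[int],
    fallback_nearest: bool = False,
) -> float:
    """Functional alias for :meth:`PopulationTable.person_years`."""
    return pop.person_years(sex, band, years, fallback_nearest=fallback_nearest)


@dataclass
class StudyConfig:
    """Run configuration: code sets, band schemes, window and flags."""

    site_codes: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(SITE_CODES)
    )
    study_window: tuple[int, int] = (2015, 2017)
    min_age: int = 40
    require_radiograph: bool = True
    accept_clinical_hip: bool = True
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "site_codes" in raw:
            cfg.site_codes = {
                k: frozenset(v) for k, v in raw["site_codes"].items()
            }
        if "study_window" in raw:
            lo, hi = raw["study_window"]
            cfg.study_window = (int(lo), int(hi))
        for key in ("min_age", "require_radiograph",
                    "accept_clinical_hip", "delimiter"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg
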