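"""Machine-readable fixtures of the published catchment-registry tables.

The development study for the Kazakh fracture-risk model surveyed the
Taldykorgan catchment (~165,000 residents): hip fractures over 2015-2017
(2015-2016 retrospective from hospital sources, 2017 prospective with
additional primary-care ascertainment) and forearm/humerus fractures over
2015-2016.  This module ships the printed per-stratum cells — population
person-years, unadjusted event counts, adjusted rates with exact 95%
intervals — plus the ascertainment constants, as fixtures for tests and
worked examples.

Population convention: the printed population column is *period*
person-years (annual populations summed over the study years), so the
:func:`population_table` splits each printed number evenly over
2015-2017; summing the three annual cells recovers the printed value.

``study_marginal_registry`` expands the printed marginal counts into a
synthetic row-per-case registry whose cross-tabulations reproduce the
published totals exactly (348 hip / 536 forearm / 174 humerus cases; 82
refusals of admission, 27 in men and 55 in women; 200 surgical cases among
the 266 admitted).  Flags below the printed marginals (which individual
was refused, operated, etc.) are allocated deterministically and carry no
information.
"""

from __future__ import annotations

import itertools
import math

import pandas as pd

from .bands import HIP_BANDS, NONHIP_BANDS
from .registry import PopulationTable, SITE_CODES

STUDY_YEARS = (2015, 2016, 2017)
NONHIP_YEARS = (2015, 2016)

# Hip table, 5-year bands, 2015-2017 combined.
# (age_lo, person_years[3y], events, printed adjusted rate, ci_low, ci_high)
_HIP_MEN = [
    (40, 15668, 10, 67, 31, 117),
    (45, 14234, 9, 68, 29, 120),
    (50, 13691, 10, 77, 35, 134),
    (55, 11371, 18, 167, 101, 261),
    (60, 8377, 18, 225, 127, 353),
    (65, 6387, 23, 378, 241, 562),
    (70, 3279, 8, 254, 105, 481),
    (75, 2665, 13, 527, 287, 884),
    (80, 1323, 10, 780, 362, 1390),
    (85, 593, 12, 2078, 1046, 3605),
    (90, 211, 3, 1536, 289, 4156),
    (95, 150, 0, None, None, None),
]
_HIP_WOMEN = [
    (40, 19142, 5, 31, 8, 61),
    (45, 17874, 4, 27, 16, 57),
    (50, 17099, 6, 42, 17, 84),
    (55, 15231, 14, 109, 60, 176),
    (60, 11984, 16, 158, 89, 247),
    (65, 10058, 25, 292, 193, 418),
    (70, 5169, 21, 502, 313, 736),
    (75, 5665, 44, 925, 692, 1212),
    (80, 2833, 38, 1515, 1096, 2042),
    (85, 1360, 31, 2663, 1867, 3684),
    (90, 357, 10, 3207, 1537, 5514),
    (95, 108, 0, None, None, None),
]
_HIP_TOTALS = {
    "male": (77949, 134, 181, 152, 213),
    "female": (106880, 214, 236, 207, 266),
}

# Forearm/humerus table, 10-year bands, 2015-2016 combined.
# site -> sex -> [(age_lo, events, printed rate, ci_low, ci_high)]
_NONHIP = {
    "forearm": {
        "male": [
            (40, 38, 192, 136, 264), (50, 38, 229, 162, 315),
            (60, 20, 206, 126, 318), (70, 3, 78, 16, 226),
            (80, 2, 165, 20, 598), (90, 0, None, None, None),
        ],
        "female": [
            (40, 90, 366, 294, 450), (50, 172, 804, 689, 934),
            (60, 97, 673, 546, 821), (70, 53, 743, 556, 971),
            (80, 20, 748, 457, 1156), (90, 3, 952, 196, 2785),
        ],
    },
    "humerus": {
        "male": [
            (40, 13, 66, 35, 113), (50, 18, 109, 64, 172),
            (60, 15, 154, 86, 255), (70, 2, 52, 6, 187),
            (80, 0, None, None, None), (90, 1, 424, 8, 2364),
        ],
        "female": [
            (40, 14, 57, 31, 96), (50, 35, 164, 114, 228),
            (60, 39, 271, 192, 370), (70, 21, 294, 182, 450),
            (80, 16, 599, 342, 972), (90, 0, None, None, None),
        ],
    },
}
_NONHIP_TOTALS = {
    ("forearm", "male"): (101, 197, 160, 239),
    ("forearm", "female"): (435, 617, 560, 678),
    ("humerus", "male"): (49, 95, 71, 126),
    ("humerus", "female"): (125, 177, 148, 211),
}

# Imputation audit: Malmö-ratio predicted vs observed rates, ages 50-90.
# (sex, age_lo, site, predicted, observed, ci_low, ci_high, significant)
_PREDICTED_OBSERVED = [
    ("male", 50, "forearm", 298, 229, 162, 315, False),
    ("male", 50, "humerus", 113, 109, 64, 172, False),
    ("male", 60, "forearm", 286, 206, 126, 318, False),
    ("male", 60, "humerus", 103, 154, 85, 255, False),
    ("male", 70, "forearm", 85, 78, 16, 226, False),
    ("male", 70, "humerus", 12, 52, 6, 187, False),
    ("male", 80, "forearm", 79, 165, 20, 598, False),
    ("male", 80, "humerus", 100, 0, 0, 305, False),
    ("female", 50, "forearm", 516, 804, 689, 934, True),
    ("female", 50, "humerus", 148, 164, 114, 228, False),
    ("female", 60, "forearm", 497, 673, 546, 821, True),
    ("female", 60, "humerus", 188, 271, 192, 370, True),
    ("female", 70, "forearm", 640, 743, 556, 971, False),
    ("female", 70, "humerus", 332, 294, 182, 450, False),
    ("female", 80, "forearm", 507, 748, 457, 1156, False),
    ("female", 80, "humerus", 338, 599, 342, 972, True),
]

#: Ascertainment and care-pathway constants of the study.
CONSTANTS = {
    "women_hip_retro_per_year": 65,       # hospital-ascertained, 2015 and 2016
    "women_hip_prospective_2017": 84,     # with primary-care ascertainment
    "women_additional_prospective": 19,
    "men_uplift_percent": 8,
    "hip_total": 348,
    "men_hip": 134,
    "women_hip": 214,
    "refused_admission": 82,
    "refused_men": 27,
    "refused_women": 55,
    "admitted": 266,
    "surgical": 200,
    "forearm_total": 536,
    "humerus_total": 174,
    "all_fractures": 1058,
}


def _hip_frame() -> pd.DataFrame:
    rows = []
    for sex, data in (("male", _HIP_MEN), ("female", _HIP_WOMEN)):
        for (lo, py, ev, rate, cl, ch), band in zip(data, HIP_BANDS):
            rows.append({
                "sex": sex, "age_lo": lo, "age_hi": band.upper,
                "site": "hip", "person_years": py, "events": ev,
                "rate_printed": rate, "ci_low_printed": cl,
                "ci_high_printed": ch,
            })
    return pd.DataFrame(rows)


def _hip_totals_frame() -> pd.DataFrame:
    rows = []
    for sex, (py, ev, rate, cl, ch) in _HIP_TOTALS.items():
        rows.append({
            "sex": sex, "age_lo": 40, "age_hi": math.inf, "site": "hip",
            "person_years": py, "events": ev, "rate_printed": rate,
            "ci_low_printed": cl, "ci_high_printed": ch,
        })
    return pd.DataFrame(rows)


def _nonhip_frame() -> pd.DataFrame:
    rows = []
    for site, by_sex in _NONHIP.items():
        for sex, data in by_sex.items():
            for (lo, ev, rate, cl, ch), band in zip(data, NONHIP_BANDS):
                rows.append({
                    "sex": sex, "age_lo": lo, "age_hi": band.upper,
                    "site": site, "events": ev, "rate_printed": rate,
                    "ci_low_printed": cl, "ci_high_printed": ch,
                })
    return pd.DataFrame(rows)


def _nonhip_totals_frame() -> pd.DataFrame:
    rows = []
    for (site, sex), (ev, rate, cl, ch) in _NONHIP_TOTALS.items():
        rows.append({
            "sex": sex, "age_lo": 40, "age_hi": math.inf, "site": site,
            "events": ev, "rate_printed": rate,
            "ci_low_printed": cl, "ci_high_printed": ch,
        })
    return pd.DataFrame(rows)


def _table4_frame() -> pd.DataFrame:
    rows = [
        {"sex": s, "age_lo": lo, "age_hi": lo + 10, "site": site,
         "predicted": p, "observed": o, "ci_low": cl, "ci_high": ch,
         "significant_printed": sig}
        for s, lo, site, p, o, cl, ch, sig in _PREDICTED_OBSERVED
    ]
    return pd.DataFrame(rows)


def fixture_tables() -> dict:
    """The published catchment tables and constants, machine readable.

    Keys: ``hip`` (per 5-year band), ``hip_totals`` (40+ marginals),
    ``nonhip`` (forearm/humerus per 10-year band), ``nonhip_totals``,
    ``predicted_observed`` (imputation audit cells) and ``constants``.
    """
    return {
        "hip": _hip_frame(),
        "hip_totals": _hip_totals_frame(),
        "nonhip": _nonhip_frame(),
        "nonhip_totals": _nonhip_totals_frame(),
        "predicted_observed": _table4_frame(),
        "constants": dict(CONSTANTS),
    }


def population_table(years: tuple[int, ...] = STUDY_YEARS) -> PopulationTable:
    """Catchment denominators: printed period person-years split evenly
    over the study years (one annual cell per year)."""
    rows = []
    for sex, data in (("male", _HIP_MEN), ("female", _HIP_WOMEN)):
        for (lo, py, *_), band in zip(data, HIP_BANDS):
            for year in years:
                rows.append({
                    "sex": sex, "age_lo": lo,
                    "age_hi": band.upper if not band.is_open else math.nan,
                    "year": year, "count": py / len(years),
                })
    return PopulationTable(pd.DataFrame(rows))


def study_marginal_registry() -> pd.DataFrame:
    """Synthetic row-per-case registry matching the published marginals.

    One row per retained case (1058 rows).  Hip events per (sex, 5-year
    band) and forearm/humerus events per (sex, 10-year band) equal the
    printed counts; admission-refusal and surgery flags are allocated
    deterministically so the care-pathway totals (82 refused: 27 men and
    55 women; 266 admitted; 200 surgical) are exact.  Ages are set to the
    band lower edge, years cycle through the observation years — both
    below the resolution of the printed tables.
    """
    counter = itertools.count(1)
    rows: list[dict] = []

    hip_rows: dict[str, list[dict]] = {"male": [], "female": []}
    for sex, data in (("male", _HIP_MEN), ("female", _HIP_WOMEN)):
        codes = itertools.cycle(sorted(SITE_CODES["hip"]))
        years = itertools.cycle(STUDY_YEARS)
        for lo, _py, events, *_ in data:
            for _ in range(events):
                hip_rows[sex].append({
                    "person_id": f"P{next(counter):05d}", "sex": sex,
                    "age": lo, "year": next(years), "icd10": next(codes),
                    "admitted": "admitted", "surgical": False,
                    "pathological": False, "resident": True,
                    "radiograph": True,
                })
    for sex, n_refused in (("male", CONSTANTS["refused_men"]),
                           ("female", CONSTANTS["refused_women"])):
        for row in hip_rows[sex][:n_refused]:
            row["admitted"] = "refused"
    admitted = [r for sex in ("male", "female") for r in hip_rows[sex]
                if r["admitted"] == "admitted"]
    assert len(admitted) == CONSTANTS["admitted"]
    for row in admitted[: CONSTANTS["surgical"]]:
        row["surgical"] = True
    rows.extend(hip_rows["male"])
    rows.extend(hip_rows["female"])

    for site, by_sex in _NONHIP.items():
        codes = itertools.cycle(sorted(SITE_CODES[site]))
        for sex, data in by_sex.items():
            years = itertools.cycle(NONHIP_YEARS)
            for lo, events, *_ in data:
                for _ in range(events):
                    rows.append({
                        "person_id": f"P{next(counter):05d}", "sex": sex,
                        "age": lo, "year": next(years),
                        "icd10": next(codes), "admitted": "not_presented",
                        "surgical": False, "pathological": False,
                        "resident": True, "radiograph": True,
                    })
    return pd.DataFrame(rows)
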