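"""Synthetic catchment-registry generator with known ground truth.

Emulates the data-generating process assumed by a two-phase fracture
survey of a catchment of roughly 165,000 residents: per (sex, age band,
site, year) stratum the true event count is Poisson with mean
rate x person-years; each event independently reaches hospital sources
with a sex-specific capture probability; hospital-captured cases receive
admission-refusal and surgery flags; a fraction of written rows are
duplicated (re-admission for the same fracture) and a small contaminant
stream of pathological fractures is injected.  Retrospective
ascertainment writes only hospital-captured events; prospective
ascertainment (additional primary-care sources, home visits) also writes
the missed events, flagged as not presenting to hospital and — for hip —
as verified clinically rather than radiographically.

True incidence is parametric, exponential in age per site and sex
(``rate(a) = r50 * exp(slope * (a - 50))``); the default curve parameters
are log-linear fits to the catchment study's own printed band rates, so
expected synthetic event counts sit near the study marginals (~350 hip
fractures over three years).  Mortality is Gompertz,
``h(a) = alpha * exp(beta * a)``, with parameters solved once so that
life expectancy at 50 is about 25 years for women and 20 for men —
plausible for the setting and clearly synthetic.

Simulation is stratum-level: no individual life histories are drawn, as
every downstream computation consumes stratum counts.  All randomness
flows from a single ``numpy`` generator seeded from the config, so a
fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import HIP_BANDS, NONHIP_BANDS, AgeBand
from .registry import SITE_CODES, PopulationTable
from . import study_data

# Exponential-in-age incidence defaults: (rate at 50 per 100k, slope per
# year), log-linear fits to the catchment study's printed band rates.
DEFAULT_INCIDENCE_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("male", "hip"): (84.6, 0.0724),
    ("female", "hip"): (38.0, 0.1079),
    ("male", "forearm"): (205.2, -0.0059),
    ("female", "forearm"): (561.2, 0.0145),
    ("male", "humerus"): (85.3, 0.0288),
    ("female", "humerus"): (109.5, 0.0485),
}

# Gompertz mortality h(a) = alpha * exp(beta * a); alpha solved so that
# e50 = 25 y (women) / 20 y (men) at beta = 0.1.
DEFAULT_GOMPERTZ: dict[str, tuple[float, float]] = {
    "female": (3.7574e-05, 0.1),
    "male": (6.8628e-05, 0.1),
}

# Hospital-capture probabilities implied by the study's uplifts:
# women 65/84 (29% uplift), men 1/1.08 (8% uplift).
DEFAULT_CAPTURE: dict[str, float] = {
    "female": 65.0 / 84.0,
    "male": 1.0 / 1.08,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic registry draw."""

    seed: int
    years: tuple[int, ...] = study_data.STUDY_YEARS
    sites: tuple[str, ...] = ("hip", "forearm", "humerus")
    #: site -> years it is surveyed (non-hip sites: first two years only)
    site_years: dict[str, tuple[int, ...]] = field(default_factory=lambda: {
        "hip": study_data.STUDY_YEARS,
        "forearm": study_data.NONHIP_YEARS,
        "humerus": study_data.NONHIP_YEARS,
    })
    incidence_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INCIDENCE_PARAMS)
    )
    capture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE)
    )
    refusal_prob: float = 82.0 / 348.0
    surgical_prob: float = 200.0 / 266.0  # among admitted
    duplicate_prob: float = 0.03
    pathological_rate: float = 0.01
    gompertz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GOMPERTZ)
    )
    terminal_age: int = 110

    def __post_init__(self) -> None:
        probs = [self.refusal_prob, self.surgical_prob,
                 self.duplicate_prob, self.pathological_rate,
                 *self.capture.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def true_rate(self, sex: str, site: str, age: float) -> float:
        """True incidence per 100,000 person-years at exact age."""
        r50, slope = self.incidence_params[(sex, site)]
        return r50 * math.exp(slope * (age - 50.0))


@dataclass
class GroundTruth:
    """What the generator knows: true per-stratum rates, capture
    fractions and expected event counts consistent with the registry in
    expectation."""

    true_rates: pd.DataFrame      # sex, age_lo, age_hi, site, rate (per 100k)
    expected_events: pd.DataFrame  # sex, age_lo, age_hi, site, expected
    capture: dict[str, float]
    n_true_events: int
    n_written: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "capture": self.capture,
            "n_true_events": self.n_true_events,
            "n_written": self.n_written,
            "true_rates": self.true_rates.replace(
                {math.inf: None}).to_dict("records"),
            "expected_events": self.expected_events.replace(
                {math.inf: None}).to_dict("records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SimulatedData:
    registry: pd.DataFrame
    population: pd.DataFrame
    life_table: pd.DataFrame
    ground_truth: GroundTruth


def _site_bands(site: str) -> tuple[AgeBand, ...]:
    return HIP_BANDS if site == "hip" else NONHIP_BANDS


def make_life_table(config: SimulationConfig) -> pd.DataFrame:
    """Gompertz annual death hazards by single year of age, 40..terminal."""
    rows = []
    for sex, (alpha, beta) in config.gompertz.items():
        for age in range(40, config.terminal_age + 1):
            rows.append({
                "sex": sex, "age": age,
                "hazard": alpha * math.exp(beta * age),
            })
    return pd.DataFrame(rows)


def simulate(config: SimulationConfig,
             ascertainment: str = "two_phase") -> SimulatedData:
    """Draw one synthetic registry under the configured study conditions.

    ``ascertainment`` selects the writing rule: ``"retrospective"``
    (hospital-captured events only, all years), ``"prospective"`` (all
    events, all years) or ``"two_phase"`` (hospital-only in all but the
    final surveyed year of each site, full capture in the final year —
    the design the capture uplift is estimated from).
    """
    if ascertainment not in ("retrospective", "prospective", "two_phase"):
        raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
    rng = np.random.default_rng(config.seed)
    pop = study_data.population_table(config.years)

    truth_rows, expected_rows, rows = [], [], []
    n_true = 0
    uid = 0
    for site in config.sites:
        bands = _site_bands(site)
        site_years = config.site_years.get(site, config.years)
        prospective_year = max(site_years)
        codes = sorted(SITE_CODES[site])
        for sex in ("male", "female"):
            cap = config.capture[sex] if site == "hip" else 1.0
            for band in bands:
                width = 5 if band.is_open else int(band.upper - band.lower)
                mid = band.lower + width / 2.0
                rate = config.true_rate(sex, site, mid)
                truth_rows.append({
                    "sex": sex, "age_lo": band.lower, "age_hi": band.upper,
                    "site": site, "rate": rate,
                })
                py_total = 0.0
                for year in site_years:
                    py = pop.person_years(sex, band, [year])
                    py_total += py
                    mean = rate / 1e5 * py
                    k = int(rng.poisson(mean))
                    n_true += k
                    for _ in range(k):
                        uid += 1
                        captured = bool(rng.random() < cap)
                        written = (
                            captured
                            if ascertainment == "retrospective"
                            else True
                            if ascertainment == "prospective"
                            else captured or year == prospective_year
                        )
                        if not written:
                            continue
                        age = int(band.lower + rng.integers(0, width))
                        if captured:
                            refused = bool(rng.random() < config.refusal_prob)
                            admitted = "refused" if refused else "admitted"
                            surgical = (not refused) and bool(
                                rng.random() < config.surgical_prob
                            )
                            radiograph = True
                        else:
                            admitted, surgical = "not_presented", False
                            # found at home: hip verified clinically
                            radiograph = site != "hip"
                        row = {
                            "person_id": f"S{uid:06d}", "sex": sex,
                            "age": age, "year": year,
                            "icd10": codes[int(rng.integers(len(codes)))],
                            "admitted": admitted, "surgical": surgical,
                            "pathological": False, "resident": True,
                            "radiograph": radiograph,
                        }
                        rows.append(row)
                        if rng.random() < config.duplicate_prob:
                            dup = dict(row)
                            dup["year"] = min(year + 1, max(site_years))
                            rows.append(dup)
                expected_rows.append({
                    "sex": sex, "age_lo": band.lower, "age_hi": band.upper,
                    "site": site, "expected": rate / 1e5 * py_total,
                })

    # pathological contaminants (excluded downstream by filtering)
    n_contam = int(rng.poisson(config.pathological_rate * max(n_true, 1)))
    for _ in range(n_contam):
        uid += 1
        site = config.sites[int(rng.integers(len(config.sites)))]
        codes = sorted(SITE_CODES[site])
        rows.append({
            "person_id": f"S{uid:06d}",
            "sex": "female" if rng.random() < 0.5 else "male",
            "age": int(rng.integers(40, 95)),
            "year": int(config.years[int(rng.integers(len(config.years)))]),
            "icd10": codes[int(rng.integers(len(codes)))],
            "admitted": "admitted", "surgical": False,
            "pathological": True, "resident": True, "radiograph": True,
        })

    registry = pd.DataFrame(rows, columns=[
        "person_id", "sex", "age", "year", "icd10", "admitted",
        "surgical", "pathological", "resident", "radiograph",
    ])
    truth = GroundTruth(
        true_rates=pd.DataFrame(truth_rows),
        expected_events=pd.DataFrame(expected_rows),
        capture=dict(config.capture),
        n_true_events=n_true,
        n_written=len(registry),
    )
    return SimulatedData(
        registry=registry,
        population=pop.frame,
        life_table=make_life_table(config),
        ground_truth=truth,
    )


def simulate_registry(
    config: SimulationConfig,
    outdir: str | Path,
    ascertainment: str = "two_phase",
) -> dict[str, Path]:
    """Write registry/population/life-table CSVs and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate(config, ascertainment=ascertainment)
    paths = {
        "registry": outdir / "registry.csv",
        "population": outdir / "population.csv",
        "life_table": outdir / "life_table.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    data.registry.to_csv(paths["registry"], index=False)
    data.population.to_csv(paths["population"], index=False)
    data.life_table.to_csv(paths["life_table"], index=False)
    data.ground_truth.to_json(paths["ground_truth"])
    return paths
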