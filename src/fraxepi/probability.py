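"""Fracture probabilities under competing mortality.

The engine treats the tabulated age-specific incidence as the hazard of a
*first* fracture (registries of this kind count persons with at least one
index fracture) and the life table as the all-cause death hazard.  Both
hazards are piecewise constant in age.  The probability of sustaining the
index fracture within horizon ``T`` from age ``a``, before dying, is the
cause-specific cumulative incidence

    P = int_0^T  rr * h_f(t) * exp( -int_0^t (rr*h_f(u) + h_d(u)) du ) dt

where ``rr`` is an optional hazard-ratio multiplier encoding a clinical
risk profile (for example a prior fragility fracture).  On each interval
where both hazards are constant the integral has the closed form

    S(t0) * rr*h_f / (rr*h_f + h_d) * (1 - exp(-(rr*h_f + h_d) * dt))

and the engine sums these terms over segments split at every hazard knot
and at the horizon — no numerical quadrature is involved.  Lifetime risk
is the same quantity integrated to a terminal age (default 110), beyond
the last tabulated band the final hazard is held constant; with any
realistic old-age death hazard the integrand is negligible there, so the
terminal-age choice is immaterial (see the tail-truncation test).

Death after fracture is not modelled differently from death before it:
this is the plain competing-hazard formulation, without post-fracture
excess mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

TERMINAL_AGE_DEFAULT = 110.0


@dataclass(frozen=True)
class HazardCurve:
    """Piecewise-constant annual hazard by age.

    ``hazards[i]`` applies on ``[knots[i], knots[i+1])``; the last value is
    held constant beyond the final knot up to ``terminal_age``.
    """

    knots: tuple[float, ...]
    hazards: tuple[float, ...]
    sex: str = ""
    terminal_age: float = TERMINAL_AGE_DEFAULT

    def __post_init__(self) -> None:
        if len(self.knots) != len(self.hazards) or not self.knots:
            raise ValueError("knots and hazards must be equal-length, non-empty")
        if any(h < 0 for h in self.hazards):
            raise ValueError("hazards must be non-negative")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if self.terminal_age <= self.knots[-1]:
            raise ValueError("terminal age must exceed the last knot")

    @classmethod
    def from_arrays(cls, knots, hazards, **kw) -> "HazardCurve":
        return cls(tuple(float(k) for k in knots),
                   tuple(float(h) for h in hazards), **kw)

    @classmethod
    def constant(cls, hazard: float, start: float = 0.0, **kw) -> "HazardCurve":
        return cls((float(start),), (float(hazard),), **kw)

    @classmethod
    def from_incidence_table(
        cls, table: pd.DataFrame, sex: str, site: str | None = None, **kw
    ) -> "HazardCurve":
        """Rates per 100,000/year become annual first-event hazards.

        Band lower edges are the knots; the terminal open band's hazard is
        held to the terminal age.
        """
        sub = table[table["sex"] == sex]
        if site is not None:
            sub = sub[sub["site"] == site]
        if sub.empty:
            raise ValueError(f"no incidence rows for sex={sex!r} site={site!r}")
        sub = sub.sort_values("age_lo")
        return cls.from_arrays(
            sub["age_lo"].to_numpy(float),
            sub["rate"].to_numpy(float) / 100_000.0,
            sex=sex, **kw,
        )

    def hazard_at(self, age: float) -> float:
        if age < self.knots[0] or age >= self.terminal_age:
            raise ValueError(
                f"age {age} outside curve support "
                f"[{self.knots[0]}, {self.terminal_age})"
            )
        idx = int(np.searchsorted(self.knots, age, side="right")) - 1
        return self.hazards[idx]

    def covers(self, start: float, end: float) -> bool:
        return self.knots[0] <= start and end <= self.terminal_age


@dataclass(frozen=True)
class LifeTable:
    """Age-specific annual death hazard for one sex.

    Construct from hazards directly or from annual death probabilities
    ``q`` via the exponential-survival conversion ``h = -ln(1 - q)``.
    """

    sex: str
    ages: tuple[float, ...]
    hazards: tuple[float, ...]

    @classmethod
    def from_hazards(cls, sex: str, ages, hazards) -> "LifeTable":
        return cls(sex, tuple(float(a) for a in ages),
                   tuple(float(h) for h in hazards))

    @classmethod
    def from_death_probabilities(cls, sex: str, ages, q) -> "LifeTable":
        q = np.asarray(q, float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("death probabilities must lie in [0, 1)")
        return cls.from_hazards(sex, ages, -np.log1p(-q))

    @classmethod
    def read_csv(cls, path: str | Path, sex: str,
                 delimiter: str = ",") -> "LifeTable":
        """Read sex, age and either a ``hazard`` or ``death_probability``
        column (the header decides which conversion applies)."""
        frame = pd.read_csv(path, sep=delimiter)
        sub = frame[frame["sex"] == sex].sort_values("age")
        if sub.empty:
            raise ValueError(f"life table has no rows for sex={sex!r}")
        if "hazard" in frame.columns:
            return cls.from_hazards(sex, sub["age"], sub["hazard"])
        if "death_probability" in frame.columns:
            return cls.from_death_probabilities(
                sex, sub["age"], sub["death_probability"]
            )
        raise ValueError(
            "life table needs a 'hazard' or 'death_probability' column"
        )

    def to_hazard_curve(
        self, terminal_age: float = TERMINAL_AGE_DEFAULT
    ) -> HazardCurve:
        # rows at or beyond the terminal age are redundant: the last
        # retained hazard is held constant up to it anyway
        pairs = [(a, h) for a, h in zip(self.ages, self.hazards)
                 if a < terminal_age]
        if not pairs:
            raise ValueError("life table has no rows below the terminal age")
        ages, hazards = zip(*pairs)
        return HazardCurve(ages, hazards, sex=self.sex,
                           terminal_age=terminal_age)


@dataclass(frozen=True)
class ProbabilityResult:
    age: float
    sex: str
    horizon: float | str  # years, or "lifetime"
    rr: float
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


def _segments(
    fracture: HazardCurve, death: HazardCurve, start: float, end: float
) -> Iterator[tuple[float, float, float, float]]:
    """Yield (t0, t1, h_f, h_d) over [start, end) split at every knot."""
    cuts = sorted(
        {start, end}
        | {k for k in fracture.knots if start < k < end}
        | {k for k in death.knots if start < k < end}
    )
    for t0, t1 in zip(cuts, cuts[1:]):
        yield t0, t1, fracture.hazard_at(t0), death.hazard_at(t0)


def cumulative_incidence(
    fracture_hazard: HazardCurve,
    death_hazard: HazardCurve,
    start_age: float,
    horizon: float,
    rr: float = 1.0,
) -> float:
    """Probability of first fracture before death within ``horizon`` years.

    Closed form on each constant-hazard segment; exact up to floating
    point.  Raises when either curve does not cover the assessment window.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if rr < 0:
        raise ValueError("relative risk must be non-negative")
    end_age = start_age + horizon
    for name, curve in (("fracture", fracture_hazard), ("death", death_hazard)):
        if not curve.covers(start_age, end_age):
            raise ValueError(
                f"{name} hazard curve does not cover "
                f"[{start_age}, {end_age}); extend the curve or terminal age"
            )
    prob = 0.0
    log_surv = 0.0  # log of combined fracture-and-death-free survival
    for t0, t1, hf, hd in _segments(fracture_hazard, death_hazard,
                                    start_age, end_age):
        dt = t1 - t0
        hf_eff = rr * hf
        total = hf_eff + hd
        surv = math.exp(log_surv)
        if total > 0.0:
            prob += surv * (hf_eff / total) * (-math.expm1(-total * dt))
            log_surv -= total * dt
    return prob


def ten_year_probability(
    incidence: pd.DataFrame,
    lifetable: LifeTable,
    age: float,
    sex: str,
    rr: float = 1.0,
    site: str | None = None,
    horizon: float = 10.0,
    terminal_age: float = TERMINAL_AGE_DEFAULT,
) -> ProbabilityResult:
    """Ten-year fracture probability at ``age`` for ``sex``.

    Builds the first-fracture hazard from an incidence table (rates per
    100,000 become annual hazards) and the death hazard from the life
    table, then evaluates the competing-risk cumulative incidence.
    """
    if age < 40:
        raise ValueError("assessment age must be at least 40")
    frac = HazardCurve.from_incidence_table(
        incidence, sex=sex, site=site, terminal_age=terminal_age
    )
    death = lifetable.to_hazard_curve(terminal_age)
    p = cumulative_incidence(frac, death, age, horizon, rr)
    return ProbabilityResult(age, sex, horizon, rr, p)


def lifetime_risk(
    incidence: pd.DataFrame,
    lifetable: LifeTable,
    sex: str,
    from_age: float = 50.0,
    rr: float = 1.0,
    site: str | None = None,
    terminal_age: float = TERMINAL_AGE_DEFAULT,
) -> ProbabilityResult:
    """Remaining lifetime fracture probability from ``from_age``.

    Integrates to the terminal age; the death hazard drives the integrand
    to zero well before it, making the truncation error negligible.
    """
    if from_age < 40:
        raise ValueError("assessment age must be at least 40")
    frac = HazardCurve.from_incidence_table(
        incidence, sex=sex, site=site, terminal_age=terminal_age
    )
    death = lifetable.to_hazard_curve(terminal_age)
    p = cumulative_incidence(frac, death, from_age,
                             terminal_age - from_age, rr)
    return ProbabilityResult(from_age, sex, "lifetime", rr, p)
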