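"""Age-band conventions for stratified incidence tables.

Bands are closed-open intervals ``[lower, upper)`` in completed years of age,
matching the usual "40-44", "45-49" labelling of registry tables.  The
terminal band of a scheme is open-ended (``upper`` is ``inf``) and is
labelled "95+" style.  Two schemes are used throughout: 5-year bands from 40
with a terminal 95+ band (hip), and 10-year bands from 40 with a terminal
90+ band (forearm and humerus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed-open age interval ``[lower, upper)`` in completed years."""

    lower: int
    upper: float  # math.inf for the open terminal band

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError(f"empty age band [{self.lower}, {self.upper})")

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper

    @property
    def is_open(self) -> bool:
        return math.isinf(self.upper)

    @property
    def label(self) -> str:
        if self.is_open:
            return f"{self.lower}+"
        return f"{self.lower}-{int(self.upper) - 1}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def make_bands(start: int, width: int, open_from: int) -> tuple[AgeBand, ...]:
    """Build a scheme of ``width``-year bands from ``start`` with an open
    terminal band beginning at ``open_from``."""
    if (open_from - start) % width != 0:
        raise ValueError("open_from must sit on a band boundary")
    closed = [
        AgeBand(lo, lo + width) for lo in range(start, open_from, width)
    ]
    return tuple(closed + [AgeBand(open_from, math.inf)])


#: 5-year scheme used for hip incidence: 40-44 ... 90-94, 95+.
HIP_BANDS: tuple[AgeBand, ...] = make_bands(40, 5, 95)

#: 10-year scheme used for forearm/humerus incidence: 40-49 ... 80-89, 90+.
NONHIP_BANDS: tuple[AgeBand, ...] = make_bands(40, 10, 90)


def find_band(bands: Sequence[AgeBand], age: float) -> AgeBand:
    """Return the band containing ``age``; raises if no band does."""
    for band in bands:
        if band.contains(age):
            return band
    raise ValueError(f"age {age} not covered by the band scheme")


def validate_partition(bands: Sequence[AgeBand], start: int = 40) -> None:
    """Check that ``bands`` partition [start, inf) without gaps or overlap."""
    ordered = sorted(bands)
    if not ordered or ordered[0].lower != start:
        raise ValueError(f"bands must start at {start}")
    for a, b in zip(ordered, ordered[1:]):
        if a.upper != b.lower:
            raise ValueError(f"gap or overlap between {a} and {b}")
    if not ordered[-1].is_open:
        raise ValueError("terminal band must be open-ended")


def nests_within(coarse: Sequence[AgeBand], fine: Sequence[AgeBand]) -> bool:
    """True when every coarse band is a union of consecutive fine bands."""
    fine_sorted = sorted(fine)
    edges = {b.lower for b in fine_sorted}
    for band in coarse:
        if band.lower not in edges:
            return False
        if not band.is_open and band.upper not in edges | {
            fine_sorted[-1].upper
        }:
            return False
        if band.is_open and not fine_sorted[-1].is_open:
            return False
    return True


def parse_band(label_lo, label_hi) -> AgeBand:
    """Build a band from the ``age_lo``/``age_hi`` CSV convention, where a
    blank, negative or non-finite ``age_hi`` marks the open terminal band.
    ``age_hi`` is the *exclusive* upper edge (so "40-44" has age_hi 45)."""
    lo = int(label_lo)
    try:
        hi = float(label_hi)
    except (TypeError, ValueError):
        return AgeBand(lo, math.inf)
    if math.isnan(hi) or hi < 0:
        return AgeBand(lo, math.inf)
    return AgeBand(lo, hi)
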