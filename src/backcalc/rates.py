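"""Yearly exit-rate (q_t) schedules: mortality anchors, cessation, scenarios.

Mortality among out-of-treatment heroin users is only fragmentarily known
(cohort studies give a minimum of 1.4% in 1985 and a maximum of 6.6% in
1995; the pre-1985 period ramps smoothly up from 1%, and post-1999 rates
fall from 1.5% back to 1%).  The default schedule linearly interpolates
those anchor points and is explicitly an approximation — any fit report
records the full schedule used so a better series can be substituted.
Permanent-cessation rates from long-term cohort reviews span 0.02-0.04
per year; sensitivity scenarios cross the two cessation values with an
optional +0.01 mortality offset, giving four q_t schedules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import LeavingSchedule, ModelError, YearGrid

__all__ = [
    "MortalityAnchors",
    "Scenario",
    "DEFAULT_ANCHORS",
    "default_mortality_anchors",
    "non_injector_mortality",
    "build_mortality",
    "build_schedule",
    "standard_scenarios",
]

#: (year, yearly death probability) anchor points for the injector-dominated
#: national extrapolation; linear between anchors, flat outside.
DEFAULT_ANCHORS: tuple[tuple[int, float], ...] = (
    (1971, 0.010),
    (1984, 0.014),
    (1985, 0.014),
    (1995, 0.066),
    (1999, 0.015),
    (2006, 0.010),
)


@dataclass(frozen=True)
class MortalityAnchors:
    """Sparse (year, rate) anchors; rates are interpolated linearly between
    anchor years and held constant outside the anchored range."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(y), float(r)) for y, r in self.points)
        if len(pts) < 1:
            raise ModelError("need at least one mortality anchor")
        years = [y for y, _ in pts]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ModelError("anchor years must be strictly increasing")
        if any(not (0.0 < r < 1.0) for _, r in pts):
            raise ModelError("anchor rates must lie strictly in (0, 1)")
        object.__setattr__(self, "points", pts)

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.points])


def default_mortality_anchors() -> MortalityAnchors:
    return MortalityAnchors(DEFAULT_ANCHORS)


@dataclass(frozen=True)
class Scenario:
    """One sensitivity setting: a constant yearly cessation rate plus an
    additive offset applied to every year's mortality."""

    name: str
    cessation_rate: float
    mortality_offset: float = 0.0
    is_default: bool = False

    def __post_init__(self) -> None:
        if self.cessation_rate < 0:
            raise ModelError("cessation_rate must be nonnegative")
        if self.mortality_offset < 0:
            raise ModelError("mortality_offset must be nonnegative")


def build_mortality(grid: YearGrid, anchors: MortalityAnchors) -> np.ndarray:
    """Yearly mortality series on the grid, linear between anchors and
    constant-extrapolated outside the anchored range."""
    return np.interp(grid.years.astype(float), anchors.years.astype(float), anchors.rates)


def non_injector_mortality(grid: YearGrid, rate: float = 0.01) -> np.ndarray:
    """Constant mortality schedule for the lower-risk non-injecting stratum."""
    if not (0.0 < rate < 1.0):
        raise ModelError("rate must lie in (0, 1)")
    return np.full(grid.n_years, rate)


def build_schedule(grid: YearGrid, mortality: Sequence[float], scenario: Scenario) -> LeavingSchedule:
    """q_t = (mortality_t + offset) + cessation, validated (q_t < 1) per year."""
    m = np.asarray(mortality, dtype=float) + scenario.mortality_offset
    c = np.full(grid.n_years, scenario.cessation_rate)
    return LeavingSchedule(grid, m, c)


def standard_scenarios() -> list[Scenario]:
    """The four cessation x mortality-offset combinations used for
    sensitivity analysis; the (0.04, +0) combination is the primary one."""
    return [
        Scenario("cess0.04", cessation_rate=0.04, mortality_offset=0.0, is_default=True),
        Scenario("cess0.02", cessation_rate=0.02, mortality_offset=0.0),
        Scenario("cess0.04+mort0.01", cessation_rate=0.04, mortality_offset=0.01),
        Scenario("cess0.02+mort0.01", cessation_rate=0.02, mortality_offset=0.01),
    ]
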