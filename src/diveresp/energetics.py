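"""Per-track respiration rates and oxygen-consumption estimates.

Respiration follows the one-breath-per-surfacing rule for resting,
travelling and foraging; logging surfacings may carry a configurable
breath multiplier (observed mean 2.1 breaths per logging surfacing,
default 1).  Oxygen consumption chains a sex-specific Gompertz
length-at-age model, a length-to-mass power law, nearest-mass matching to
a reference animal within a relative tolerance, and the respirometry
identity VO2 = rate x V_T x E_O2 with activity levels mapped as
resting -> 1, travelling/foraging -> 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .tracks import Track

__all__ = [
    "GompertzParams",
    "GrowthModelConfig",
    "ReferenceAnimal",
    "RespirationResult",
    "VO2Result",
    "MassMatchError",
    "respiration_rate",
    "predict_length",
    "predict_mass",
    "match_reference",
    "vo2",
    "activity_level",
]

ACTIVITY_LEVELS = (1, 2, 3)


class MassMatchError(LookupError):
    """No reference animal within the mass tolerance (an expected path:
    such whales are excluded from VO2 analysis, not imputed)."""


@dataclass(frozen=True)
class GompertzParams:
    """Length-at-age L(t) = A * exp(-b * exp(-c * t)), cm and years."""

    asymptotic_length: float  # A, cm
    shape: float              # b
    rate: float               # c, per year

    def __post_init__(self) -> None:
        if self.asymptotic_length <= 0 or self.rate <= 0:
            raise ValueError("A and c must be positive")


@dataclass(frozen=True)
class GrowthModelConfig:
    gompertz: Mapping[str, GompertzParams]  # keyed by sex
    mass_coefficient: float                 # a in mass = a * length**k (kg, cm)
    mass_exponent: float                    # k

    def __post_init__(self) -> None:
        if self.mass_coefficient <= 0 or self.mass_exponent <= 0:
            raise ValueError("mass parameters must be positive")


@dataclass(frozen=True)
class ReferenceAnimal:
    """A measured animal supplying activity-specific V_T and E_O2.

    ``V_T[level]`` is litres per breath; ``E_O2[level]`` is the extracted
    fraction of inhaled oxygen; level 2 may be absent, in which case it is
    taken as the mean of levels 1 and 3.  ``T_O2`` is carried for
    completeness but unused by the implemented formula.
    """

    name: str
    sex: str
    age_class: str
    body_mass: float  # kg
    V_T: Mapping[int, float]
    E_O2: Mapping[int, float]
    T_O2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        for lvl, v in self.V_T.items():
            if v <= 0:
                raise ValueError(f"V_T level {lvl} must be positive")
        for lvl, e in self.E_O2.items():
            if not 0 < e < 1:
                raise ValueError(f"E_O2 level {lvl} must be in (0, 1)")

    def _level(self, table: Mapping[int, float], level: int) -> float:
        if level in table:
            return table[level]
        if level == 2 and 1 in table and 3 in table:
            return 0.5 * (table[1] + table[3])
        raise KeyError(
            f"reference {self.name}: activity level {level} missing and no "
            "level-1/3 averaging fallback available")

    def tidal_volume(self, level: int) -> float:
        return self._level(self.V_T, level)

    def oxygen_extraction(self, level: int) -> float:
        return self._level(self.E_O2, level)


@dataclass
class RespirationResult:
    whale_id: str
    track_index: int
    behaviour: Optional[str]
    n_breaths: float
    respiration_rate: float  # breaths per minute


@dataclass
class VO2Result:
    whale_id: str
    track_index: int
    behaviour: str
    VO2: float  # L O2 per minute
    matched_reference: str
    V_T_used: float
    E_O2_used: float


def respiration_rate(
    track: Track,
    n_logging_dives: int = 0,
    logging_multiplier: float = 1.0,
) -> RespirationResult:
    """Breaths per minute over one analysis-eligible track.

    Each surfacing carries one breath; surfacings that follow logging
    dives contribute ``logging_multiplier`` breaths instead.
    """
    if not track.eligible:
        raise ValueError(
            f"track {track.whale_id}/{track.track_index} is below the minimum "
            "duration and excluded from respiration analysis")
    if not 0 <= n_logging_dives <= track.n_surface_intervals:
        raise ValueError("n_logging_dives out of range")
    n_breaths = (track.n_surface_intervals - n_logging_dives) \
        + n_logging_dives * logging_multiplier
    rate = n_breaths / (track.cumulative_duration / 60.0)
    return RespirationResult(track.whale_id, track.track_index, track.behaviour,
                             n_breaths, rate)


def predict_length(age: float, sex: str, growth: GrowthModelConfig) -> float:
    """Gompertz length at age, cm."""
    if age < 0:
        raise ValueError("age must be non-negative")
    try:
        g = growth.gompertz[sex]
    except KeyError:
        raise KeyError(f"no Gompertz parameters for sex {sex!r}") from None
    return g.asymptotic_length * math.exp(-g.shape * math.exp(-g.rate * age))


def predict_mass(length: float, growth: GrowthModelConfig) -> float:
    """Power-law mass from length: a * length**k, kg from cm."""
    if length <= 0:
        raise ValueError("length must be positive")
    return growth.mass_coefficient * length ** growth.mass_exponent


def match_reference(
    mass: float,
    sex: str,
    age_class: str,
    references: Sequence[ReferenceAnimal],
    tolerance: float = 0.15,
) -> ReferenceAnimal:
    """Closest same-class reference within the relative mass tolerance.

    The relative difference uses the reference mass as denominator.
    Raises :class:`MassMatchError` when no reference qualifies.
    """
    if not references:
        raise ValueError("reference table is empty")
    candidates = [
        (abs(mass - r.body_mass) / r.body_mass, r)
        for r in references
        if r.sex == sex and r.age_class == age_class
    ]
    candidates = [(d, r) for d, r in candidates if d <= tolerance]
    if not candidates:
        raise MassMatchError(
            f"no {age_class} {sex} reference within {tolerance:.0%} of {mass:.0f} kg")
    return min(candidates, key=lambda dr: dr[0])[1]


def activity_level(behaviour: str) -> int:
    """Resting maps to level 1; travelling and foraging to level 2."""
    levels = {"resting": 1, "travelling": 2, "foraging": 2}
    try:
        return levels[behaviour]
    except KeyError:
        raise ValueError(f"no activity level for behaviour {behaviour!r}") from None


def vo2(rate: float, ref: ReferenceAnimal, behaviour: str,
        whale_id: str = "", track_index: int = -1) -> VO2Result:
    """Oxygen consumption, L O2/min: rate x V_T(level) x E_O2(level)."""
    if rate < 0:
        raise ValueError("respiration rate must be non-negative")
    level = activity_level(behaviour)
    v_t = ref.tidal_volume(level)
    e_o2 = ref.oxygen_extraction(level)
    return VO2Result(whale_id, track_index, behaviour,
                     VO2=rate * v_t * e_o2,
                     matched_reference=ref.name, V_T_used=v_t, E_O2_used=e_o2)
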