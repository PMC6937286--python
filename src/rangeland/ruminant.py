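"""Ruminant diet selection and metabolizable-energy balance.

Functional forms follow the GRAZPLAN family: potential intake scales
with metabolic weight and body condition, realized intake of each
forage pool is limited jointly by a saturating relative-availability
term (biomass) and a linear relative-ingestibility term
(digestibility), dietary energy content is linear in digestibility,
and maintenance requirement scales with metabolic weight with
multiplicative pregnancy and lactation loadings.  All coefficients are
exposed on :class:`IntakeParams`.

The headline output is diet sufficiency,

    diet_sufficiency = (ME_intake - ME_req) / ME_req,

positive when the diet supports weight gain, negative when the animal
is expected to lose weight, and exactly -1 when intake is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AnimalClass",
    "HerdConfig",
    "IntakeParams",
    "ForagePool",
    "ForagePoolView",
    "DietSelection",
    "EnergyBalance",
    "normal_weight_for_age",
    "potential_intake",
    "relative_availability",
    "relative_ingestibility",
    "select_diet",
    "me_from_digestibility",
    "me_requirement",
    "diet_sufficiency",
    "DAYS_PER_MONTH",
]

#: Mean length of a month, used to convert daily intake to monthly offtake.
DAYS_PER_MONTH = 30.44

#: Cattle gestation length in months, used to place the pregnancy window.
GESTATION_MONTHS = 9


@dataclass(frozen=True)
class AnimalClass:
    """One age/sex class of a static herd."""

    label: str
    sex: str  # female | male | castrate
    age_months: float
    weight: float  # kg
    standard_ref_weight: float  # kg, breed mature weight
    conception_month: int | None = None  # month-of-year 1-12
    calving_interval: int | None = None  # months
    lactation_duration: int | None = None  # months

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "castrate"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.weight <= 0 or self.standard_ref_weight <= 0:
            raise ValueError("weights must be positive")
        if self.age_months < 0:
            raise ValueError("age must be non-negative")
        breeding = (self.conception_month, self.calving_interval,
                    self.lactation_duration)
        if any(b is not None for b in breeding):
            if any(b is None for b in breeding):
                raise ValueError(
                    "conception_month, calving_interval and "
                    "lactation_duration must be given together"
                )
            if not 1 <= self.conception_month <= 12:
                raise ValueError("conception_month must be in 1..12")
            if self.calving_interval < GESTATION_MONTHS:
                raise ValueError(
                    "calving_interval shorter than gestation"
                )
            if self.lactation_duration < 0:
                raise ValueError("lactation_duration must be >= 0")

    @property
    def is_breeding_female(self) -> bool:
        return self.sex == "female" and self.conception_month is not None


@dataclass(frozen=True)
class HerdConfig:
    """Static herd: (class, proportion) pairs plus a stocking density."""

    classes: tuple[tuple[AnimalClass, float], ...]
    stocking_density: float  # animals/ha

    def __post_init__(self) -> None:
        if self.stocking_density < 0:
            raise ValueError("stocking_density must be >= 0")
        if not self.classes:
            raise ValueError("herd needs at least one class")
        total = sum(p for _, p in self.classes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"class proportions must sum to 1 (got {total:.6f})"
            )
        if any(p < 0 for _, p in self.classes):
            raise ValueError("proportions must be non-negative")

    def with_density(self, density: float) -> "HerdConfig":
        return HerdConfig(self.classes, density)


@dataclass(frozen=True)
class IntakeParams:
    """Coefficients of the intake/energy functional forms."""

    i_scale: float = 0.14  # kg DM/day per kg^0.75 of SRW
    condition_cap: float = 1.2
    b_sat: float = 1000.0  # kg/ha biomass half-saturation scale
    q_slope: float = 1.7  # ingestibility penalty per unit digestibility
    d_ref: float = 0.8  # reference digestibility (ingestibility = 1)
    me_slope: float = 17.2  # MJ/kg DM per unit digestibility
    me_intercept: float = -1.71  # MJ/kg DM
    c_m: float = 0.55  # MJ/day per kg^0.75 maintenance
    pregnancy_factor: float = 1.15
    lactation_factor: float = 1.4
    maturation_rate: float = 0.1  # 1/month, logistic growth to SRW
    birth_weight_frac: float = 0.07  # of SRW, anchors the logistic

    def __post_init__(self) -> None:
        if self.i_scale <= 0 or self.c_m <= 0:
            raise ValueError("i_scale and c_m must be positive")
        if self.b_sat <= 0:
            raise ValueError("b_sat must be positive")
        if not 0 < self.d_ref <= 1:
            raise ValueError("d_ref must lie in (0, 1]")


@dataclass(frozen=True)
class ForagePool:
    """One selectable forage pool as the animal sees it."""

    biomass: float  # kg DM/ha
    digestibility: float  # fraction
    crude_protein: float  # fraction

    def __post_init__(self) -> None:
        if self.biomass < 0:
            raise ValueError("biomass must be >= 0")
        if not 0.0 <= self.digestibility <= 1.0:
            raise ValueError("digestibility must lie in [0, 1]")


@dataclass(frozen=True)
class ForagePoolView:
    """Live and standing-dead pools offered for diet selection."""

    live: ForagePool
    dead: ForagePool

    @property
    def pools(self) -> dict[str, ForagePool]:
        return {"live": self.live, "dead": self.dead}


@dataclass(frozen=True)
class DietSelection:
    """Realized (or demanded) intake split across pools, kg DM/head/day."""

    intake: dict[str, float]
    diet_digestibility: float
    diet_crude_protein: float

    @property
    def total_intake(self) -> float:
        return sum(self.intake.values())

    def scaled(self, factor: float) -> "DietSelection":
        """Uniformly scale intakes (diet composition preserved)."""
        return DietSelection(
            {k: v * factor for k, v in self.intake.items()},
            self.diet_digestibility,
            self.diet_crude_protein,
        )


@dataclass(frozen=True)
class EnergyBalance:
    """Metabolizable-energy budget of one class (or herd mean) per head."""

    me_intake: float  # MJ/head/day
    me_req: float  # MJ/head/day
    diet_sufficiency: float  # (intake - req)/req


def normal_weight_for_age(animal: AnimalClass,
                          params: IntakeParams | None = None) -> float:
    """Expected weight at the animal's age: logistic growth toward the
    standard reference weight, anchored at a birth weight fraction."""
    p = params or IntakeParams()
    # logistic W(a) = SRW / (1 + exp(-k (a - a0))), a0 set by W(0)
    k = p.maturation_rate
    a0 = math.log(1.0 / p.birth_weight_frac - 1.0) / k
    return animal.standard_ref_weight / (1.0 + math.exp(-k * (animal.age_months - a0)))


def potential_intake(animal: AnimalClass,
                     params: IntakeParams | None = None) -> float:
    """Maximum dry-matter intake, kg DM/head/day.

    I_max = i_scale × SRW^0.75 × condition_factor, where the condition
    factor is weight relative to the normal weight for age, capped.
    """
    p = params or IntakeParams()
    if animal.weight <= 0 or animal.standard_ref_weight <= 0:
        raise ValueError("weights must be positive")
    condition = min(p.condition_cap,
                    animal.weight / normal_weight_for_age(animal, p))
    return p.i_scale * animal.standard_ref_weight ** 0.75 * condition


def relative_availability(biomass: float,
                          params: IntakeParams | None = None) -> float:
    """Saturating limitation of intake by pool biomass, in [0, 1)."""
    p = params or IntakeParams()
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    return 1.0 - math.exp(-biomass / p.b_sat)


def relative_ingestibility(digestibility: float,
                           params: IntakeParams | None = None) -> float:
    """Linear penalty on intake for digestibility below the reference."""
    p = params or IntakeParams()
    if not 0.0 <= digestibility <= 1.0:
        raise ValueError("digestibility must lie in [0, 1]")
    return min(1.0, max(0.0, 1.0 - p.q_slope * (p.d_ref - digestibility)))


def select_diet(forage: ForagePoolView, animal: AnimalClass,
                params: IntakeParams | None = None) -> DietSelection:
    """Diet selection across the live and standing-dead pools.

    Each pool's unconstrained share is RA(biomass) × RQ(digestibility);
    shares are normalized only when they would exceed the potential
    intake, so total intake never exceeds I_max.  Because RQ is
    increasing in digestibility, more digestible pools receive at least
    their biomass-proportional share.
    """
    p = params or IntakeParams()
    imax = potential_intake(animal, p)
    raw = {
        name: relative_availability(pool.biomass, p)
        * relative_ingestibility(pool.digestibility, p)
        for name, pool in forage.pools.items()
    }
    total_raw = sum(raw.values())
    scale = imax if total_raw <= 1.0 else imax / total_raw
    intake = {name: r * scale for name, r in raw.items()}
    total = sum(intake.values())
    if total > 0:
        dig = sum(intake[n] * forage.pools[n].digestibility
                  for n in intake) / total
        cp = sum(intake[n] * forage.pools[n].crude_protein
                 for n in intake) / total
    else:
        dig = 0.0
        cp = 0.0
    return DietSelection(intake=intake, diet_digestibility=dig,
                         diet_crude_protein=cp)


def me_from_digestibility(digestibility: float,
                          params: IntakeParams | None = None) -> float:
    """Metabolizable-energy density of forage, MJ/kg DM (floored at 0)."""
    p = params or IntakeParams()
    if not 0.0 <= digestibility <= 1.0:
        raise ValueError("digestibility must lie in [0, 1]")
    return max(0.0, p.me_slope * digestibility + p.me_intercept)


def _breeding_phase(animal: AnimalClass, month_of_year: int) -> tuple[bool, bool]:
    """(pregnant, lactating) for a breeding female in a given calendar
    month, assuming a stable annualized cycle anchored at the average
    conception month and repeating every calving interval."""
    phase = (month_of_year - animal.conception_month) % animal.calving_interval
    pregnant = phase < GESTATION_MONTHS
    lact_end = GESTATION_MONTHS + animal.lactation_duration
    lactating = GESTATION_MONTHS <= phase < min(lact_end, animal.calving_interval)
    return pregnant, lactating


def me_requirement(animal: AnimalClass, month_of_year: int = 1,
                   params: IntakeParams | None = None) -> float:
    """Maintenance metabolizable-energy requirement, MJ/head/day.

    ME_req = c_m × W^0.75, multiplied by the pregnancy factor during
    gestation and the lactation factor while lactating (breeding
    females only; other classes are independent of the month).
    """
    p = params or IntakeParams()
    if animal.weight <= 0:
        raise ValueError("weight must be positive")
    req = p.c_m * animal.weight ** 0.75
    if animal.is_breeding_female:
        if not 1 <= month_of_year <= 12:
            raise ValueError("month_of_year must be in 1..12")
        pregnant, lactating = _breeding_phase(animal, month_of_year)
        if pregnant:
            req *= p.pregnancy_factor
        if lactating:
            req *= p.lactation_factor
    return req


def diet_sufficiency(me_intake: float, me_req: float) -> float:
    """(ME_intake − ME_req) / ME_req; −1 at zero intake, 0 at maintenance."""
    if me_req <= 0:
        raise ValueError("me_req must be positive")
    return (me_intake - me_req) / me_req
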