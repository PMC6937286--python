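"""Monthly coupling of forage growth and the grazing herd.

Each simulated month: (1) the forage grows; (2) each herd class selects
a diet from the live/standing-dead pools; (3) demanded offtake is
truncated proportionally if it would push standing biomass below the
management threshold (the manager halts grazing at the residual-biomass
floor); (4) the energy balance is evaluated on realized intake;
(5) the month is recorded; (6) the realized grazing intensity feeds
back into next month's growth.  The loop is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .forage import (
    ClimateSeries,
    ForageState,
    GrassParams,
    SoilProfile,
    apply_offtake,
    crude_protein,
    live_digestibility,
    spin_up,
    step_growth,
)
from .ruminant import (
    DAYS_PER_MONTH,
    EnergyBalance,
    ForagePool,
    ForagePoolView,
    HerdConfig,
    IntakeParams,
    diet_sufficiency,
    me_from_digestibility,
    me_requirement,
    select_diet,
)

__all__ = [
    "GrazingSchedule",
    "ManagementThreshold",
    "MonthRecord",
    "SimulationResult",
    "run_simulation",
    "run_scheduled",
    "months_insufficient",
]


@dataclass(frozen=True)
class ManagementThreshold:
    """Minimum residual standing biomass (kg DM/ha) left after offtake."""

    residual_biomass: float = 300.0

    def __post_init__(self) -> None:
        if self.residual_biomass < 0:
            raise ValueError("residual_biomass must be >= 0")


@dataclass
class GrazingSchedule:
    """Scheduled grazing events: (year, month) -> intensity fraction.

    An event's intensity is the fraction of standing biomass removed
    that month.  Months absent from ``events`` are ungrazed.
    """

    events: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, inten in self.events.items():
            if not 0.0 <= inten <= 1.0:
                raise ValueError(
                    f"intensity {inten} out of [0, 1] for month {key}"
                )

    def intensity(self, year: int, month: int) -> float:
        return self.events.get((year, month), 0.0)

    def grazed_months(self) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.events.items() if v > 0)

    def monthly_climatology(self) -> dict[int, float]:
        """Mean intensity by month-of-year (for spin-up forcing)."""
        acc: dict[int, list[float]] = {}
        for (_, m), v in self.events.items():
            acc.setdefault(m, []).append(v)
        return {m: sum(v) / len(v) for m, v in acc.items()}

    def copy(self) -> "GrazingSchedule":
        return GrazingSchedule(dict(self.events))


@dataclass(frozen=True)
class MonthRecord:
    year: int
    month: int
    live_biomass: float
    dead_biomass: float
    live_cp: float
    dead_cp: float
    live_digestibility: float
    intake_per_head: float  # kg DM/head/day, herd-weighted, realized
    intake_demanded_per_head: float
    offtake: float  # kg/ha/month, realized
    offtake_demanded: float
    me_intake: float  # MJ/head/day, herd-weighted
    me_req: float
    diet_sufficiency: float
    restricted: bool


@dataclass
class SimulationResult:
    """Monthly time series emitted by a simulation run."""

    records: list[MonthRecord]
    herd_driven: bool
    final_state: ForageState

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def diet_sufficiencies(self) -> list[float]:
        return [r.diet_sufficiency for r in self.records]

    def standing_biomass(self, year: int, month: int) -> float:
        """Total standing (live + dead) biomass at a given month, after
        that month's offtake."""
        for r in self.records:
            if (r.year, r.month) == (year, month):
                return r.live_biomass + r.dead_biomass
        raise KeyError(f"({year}, {month}) not in simulated span")


def _forage_view(state: ForageState, grass: GrassParams) -> ForagePoolView:
    return ForagePoolView(
        live=ForagePool(
            biomass=state.live_biomass,
            digestibility=live_digestibility(state.live_n, grass),
            crude_protein=crude_protein(state.live_n),
        ),
        dead=ForagePool(
            biomass=state.dead_biomass,
            digestibility=grass.digest_dead,
            crude_protein=crude_protein(state.dead_n),
        ),
    )


def run_simulation(
    climate: ClimateSeries,
    soil: SoilProfile,
    grass: GrassParams,
    herd: HerdConfig,
    threshold: ManagementThreshold = ManagementThreshold(),
    months: int | None = None,
    do_spin_up: bool = True,
    intake_params: IntakeParams | None = None,
    initial_state: ForageState | None = None,
) -> SimulationResult:
    """Herd-driven coupled simulation over ``months`` of ``climate``.

    With ``do_spin_up`` the first 12 months of the climate are used as
    an ungrazed repeated climatology to equilibrate the forage state
    before the experimental period starts at the first climate month.
    """
    ip = intake_params or IntakeParams()
    if herd.stocking_density < 0:
        raise ValueError("stocking density must be >= 0")
    n = months if months is not None else len(climate)
    if n > len(climate):
        raise ValueError(
            f"climate covers {len(climate)} months, {n} requested"
        )
    if initial_state is not None:
        state = initial_state
    elif do_spin_up:
        clim_year = ClimateSeries(
            months=climate.months[:12],
            precip=climate.precip[:12],
            temp_mean=climate.temp_mean[:12],
        )
        state = spin_up(clim_year, soil, grass).state
    else:
        state = ForageState(live_biomass=100.0, dead_biomass=50.0,
                            root_biomass=100.0, live_n=grass.n_live_max,
                            dead_n=grass.dead_n)

    records: list[MonthRecord] = []
    for i in range(n):
        year, month = climate.months[i]
        state = step_growth(state, climate.precip[i], climate.temp_mean[i],
                            soil, grass)
        view = _forage_view(state, grass)

        # per-class demanded diets
        diets = []
        for animal, prop in herd.classes:
            diets.append((animal, prop, select_diet(view, animal, ip)))
        demand_per_ha = sum(
            prop * d.total_intake for _, prop, d in diets
        ) * herd.stocking_density * DAYS_PER_MONTH

        standing = state.standing_biomass
        allowed = max(0.0, standing - threshold.residual_biomass)
        if demand_per_ha > allowed:
            factor = allowed / demand_per_ha if demand_per_ha > 0 else 0.0
            restricted = True
        else:
            factor = 1.0
            restricted = False
        realized_per_ha = demand_per_ha * factor

        # herd-weighted energy balance on realized intake
        mi = mr = intake_head = demand_head = 0.0
        for animal, prop, diet in diets:
            realized = diet.scaled(factor)
            class_mi = sum(
                realized.intake[name]
                * me_from_digestibility(view.pools[name].digestibility, ip)
                for name in realized.intake
            )
            class_mr = me_requirement(animal, month, ip)
            mi += prop * class_mi
            mr += prop * class_mr
            intake_head += prop * realized.total_intake
            demand_head += prop * diet.total_intake
        suff = diet_sufficiency(mi, mr)

        state = apply_offtake(state, realized_per_ha,
                              threshold=threshold.residual_biomass)
        records.append(MonthRecord(
            year=year, month=month,
            live_biomass=state.live_biomass,
            dead_biomass=state.dead_biomass,
            live_cp=view.live.crude_protein,
            dead_cp=view.dead.crude_protein,
            live_digestibility=view.live.digestibility,
            intake_per_head=intake_head,
            intake_demanded_per_head=demand_head,
            offtake=realized_per_ha,
            offtake_demanded=demand_per_ha,
            me_intake=mi, me_req=mr, diet_sufficiency=suff,
            restricted=restricted,
        ))
    return SimulationResult(records, herd_driven=True, final_state=state)


def run_scheduled(
    climate: ClimateSeries,
    soil: SoilProfile,
    grass: GrassParams,
    schedule: GrazingSchedule,
    months: int | None = None,
    threshold: ManagementThreshold = ManagementThreshold(0.0),
    do_spin_up: bool = True,
    initial_state: ForageState | None = None,
) -> SimulationResult:
    """Schedule-driven simulation: offtake each month is a prescribed
    fraction of standing biomass (no herd physiology).  Used by the
    calibration routine and for spin-up forcing.
    """
    n = months if months is not None else len(climate)
    if n > len(climate):
        raise ValueError(
            f"climate covers {len(climate)} months, {n} requested"
        )
    if initial_state is not None:
        state = initial_state
    elif do_spin_up:
        clim_year = ClimateSeries(
            months=climate.months[:12],
            precip=climate.precip[:12],
            temp_mean=climate.temp_mean[:12],
        )
        state = spin_up(clim_year, soil, grass,
                        schedule=schedule.monthly_climatology(),
                        threshold=threshold.residual_biomass).state
    else:
        state = ForageState(live_biomass=100.0, dead_biomass=50.0,
                            root_biomass=100.0, live_n=grass.n_live_max,
                            dead_n=grass.dead_n)

    records: list[MonthRecord] = []
    for i in range(n):
        year, month = climate.months[i]
        state = step_growth(state, climate.precip[i], climate.temp_mean[i],
                            soil, grass)
        view = _forage_view(state, grass)
        inten = schedule.intensity(year, month)
        standing = state.standing_biomass
        demanded = inten * standing
        allowed = max(0.0, standing - threshold.residual_biomass)
        realized = min(demanded, allowed)
        restricted = realized < demanded - 1e-12
        state = apply_offtake(state, realized,
                              threshold=threshold.residual_biomass)
        records.append(MonthRecord(
            year=year, month=month,
            live_biomass=state.live_biomass,
            dead_biomass=state.dead_biomass,
            live_cp=view.live.crude_protein,
            dead_cp=view.dead.crude_protein,
            live_digestibility=view.live.digestibility,
            intake_per_head=0.0, intake_demanded_per_head=0.0,
            offtake=realized, offtake_demanded=demanded,
            me_intake=0.0, me_req=1.0, diet_sufficiency=0.0,
            restricted=restricted,
        ))
    return SimulationResult(records, herd_driven=False, final_state=state)


def months_insufficient(result: SimulationResult) -> int:
    """Number of months with diet sufficiency strictly below zero.

    Only defined for herd-driven runs (a scheduled run has no herd and
    no energy balance).
    """
    if not result.herd_driven:
        raise ValueError(
            "months_insufficient requires a herd-driven simulation"
        )
    return sum(1 for r in result.records if r.diet_sufficiency < 0.0)
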