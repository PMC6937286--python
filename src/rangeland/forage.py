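"""Reduced monthly herbaceous forage production.

A deliberately compact production stage in the spirit of grassland
ecosystem models: growth is limited by plant-available moisture (a
texture-derived soil bucket) and a unimodal temperature response, live
shoots senesce into a standing-dead pool, standing dead decays, and
shoot nitrogen tracks the balance of new and old tissue.  Three grazing
feedbacks act on the month following a grazing event: a penalty on
potential production, a shift of allocation toward roots, and a boost to
shoot nitrogen (compensatory quality response).

Units throughout: biomass kg DM/ha, water mm, nitrogen g N/g DM,
temperature °C, rates fraction/month.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "SoilProfile",
    "ClimateSeries",
    "GrassParams",
    "ForageState",
    "N_TO_PROTEIN",
    "water_balance",
    "bucket_capacity",
    "step_growth",
    "crude_protein",
    "live_digestibility",
    "spin_up",
]

#: Standard nitrogen-to-crude-protein conversion factor for feedstuffs.
N_TO_PROTEIN = 6.25


@dataclass(frozen=True)
class SoilProfile:
    """Soil texture and bulk properties of the rooting zone."""

    sand_fraction: float
    silt_fraction: float
    clay_fraction: float
    bulk_density: float = 1.4  # g/cm^3
    ph: float = 6.5

    def __post_init__(self) -> None:
        fracs = (self.sand_fraction, self.silt_fraction, self.clay_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError("texture fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(
                f"sand+silt+clay must sum to 1 (got {sum(fracs):.6f})"
            )
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        if not 3.0 <= self.ph <= 10.0:
            raise ValueError("ph outside plausible range [3, 10]")


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly precipitation and mean temperature driving growth.

    ``months`` is an ordered, gap-free sequence of (year, month 1-12).
    """

    months: tuple[tuple[int, int], ...]
    precip: tuple[float, ...]  # mm/month
    temp_mean: tuple[float, ...]  # degC

    def __post_init__(self) -> None:
        n = len(self.months)
        if len(self.precip) != n or len(self.temp_mean) != n:
            raise ValueError("months, precip and temp_mean must align")
        if n == 0:
            raise ValueError("climate series is empty")
        for i, (y, m) in enumerate(self.months):
            if not 1 <= m <= 12:
                raise ValueError(f"month index {m} out of range at row {i}")
            if i > 0:
                py, pm = self.months[i - 1]
                expect = (py, pm + 1) if pm < 12 else (py + 1, 1)
                if (y, m) != expect:
                    raise ValueError(
                        f"climate series has a gap at row {i}: "
                        f"expected {expect}, got {(y, m)}"
                    )
        for i, (p, t) in enumerate(zip(self.precip, self.temp_mean)):
            if not math.isfinite(p) or p < 0:
                raise ValueError(f"precip must be finite and >= 0 (row {i})")
            if not math.isfinite(t):
                raise ValueError(f"temperature must be finite (row {i})")

    def __len__(self) -> int:
        return len(self.months)

    def index_of(self, year: int, month: int) -> int:
        try:
            return self.months.index((year, month))
        except ValueError:
            raise KeyError(f"({year}, {month}) not in climate series") from None

    @classmethod
    def from_columns(
        cls,
        years: Sequence[int],
        months: Sequence[int],
        precip: Sequence[float],
        temp: Sequence[float],
    ) -> "ClimateSeries":
        return cls(
            months=tuple(zip([int(y) for y in years], [int(m) for m in months])),
            precip=tuple(float(p) for p in precip),
            temp_mean=tuple(float(t) for t in temp),
        )


@dataclass(frozen=True)
class GrassParams:
    """Parameters of the single tropical-grass forage type.

    Defaults are tuned so a semi-arid bimodal-rainfall site with ~600 mm
    annual rain carries peak standing biomass of order 10^3 kg/ha.
    """

    rue: float = 5.0  # kg DM/ha per mm effective moisture
    temp_opt: float = 25.0  # degC
    temp_width: float = 12.0  # degC
    senescence_rate: float = 0.15  # fraction of live/month
    dead_decay_rate: float = 0.10  # fraction of dead/month
    root_turnover_rate: float = 0.10  # fraction of root/month
    n_live_max: float = 0.020  # g N/g DM (new growth)
    n_live_min: float = 0.005  # g N/g DM (dormant tissue)
    n_decline_rate: float = 0.20  # monthly relaxation toward n_live_min
    dead_n: float = 0.006  # g N/g DM of the standing-dead pool
    digest_live_max: float = 0.65
    digest_dead: float = 0.45
    root_shoot_target: float = 0.5
    graze_prod_penalty: float = 0.8  # alpha
    graze_rootshoot_shift: float = 0.2  # beta
    graze_n_boost: float = 0.1  # gamma
    moisture_uptake_rain: float = 0.9  # share of this month's rain transpired
    moisture_uptake_store: float = 0.5  # share of stored water transpired

    def __post_init__(self) -> None:
        for name in ("senescence_rate", "dead_decay_rate", "root_turnover_rate",
                     "n_decline_rate", "moisture_uptake_rain",
                     "moisture_uptake_store"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("digest_live_max", "digest_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.digest_dead > self.digest_live_max:
            raise ValueError("digest_dead must not exceed digest_live_max")
        if self.rue < 0 or self.temp_width <= 0:
            raise ValueError("rue must be >= 0 and temp_width > 0")
        if self.root_shoot_target <= 0:
            raise ValueError("root_shoot_target must be positive")
        if self.graze_prod_penalty < 0 or self.graze_n_boost < 0:
            raise ValueError("grazing feedback coefficients must be >= 0")
        if not 0.0 <= self.n_live_min <= self.n_live_max:
            raise ValueError("require 0 <= n_live_min <= n_live_max")


@dataclass(frozen=True)
class ForageState:
    """Instantaneous state of the forage system on one hectare."""

    live_biomass: float = 0.0  # kg DM/ha
    dead_biomass: float = 0.0  # kg DM/ha
    root_biomass: float = 0.0  # kg DM/ha
    live_n: float = 0.02  # g N/g DM
    dead_n: float = 0.006  # g N/g DM
    soil_water: float = 0.0  # mm
    last_graze_intensity: float = 0.0  # fraction of standing biomass removed

    def __post_init__(self) -> None:
        for name in ("live_biomass", "dead_biomass", "root_biomass",
                     "soil_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.last_graze_intensity <= 1.0:
            raise ValueError("last_graze_intensity must lie in [0, 1]")

    @property
    def standing_biomass(self) -> float:
        return self.live_biomass + self.dead_biomass


def bucket_capacity(soil: SoilProfile) -> float:
    """Plant-available water capacity (mm) of a notional 30-cm root zone.

    Texture-ordered: clay holds the most plant-available water, sand the
    least.
    """
    return 100.0 * (
        0.35 * soil.clay_fraction
        + 0.25 * soil.silt_fraction
        + 0.10 * soil.sand_fraction
    )


def water_balance(
    state: ForageState,
    precip: float,
    soil: SoilProfile,
    params: GrassParams | None = None,
) -> tuple[ForageState, float]:
    """One month of the soil-water bucket.

    Plants transpire a fixed share of this month's rain plus a share of
    the water stored in the bucket; the remainder refills the bucket up
    to its texture-derived capacity and anything beyond drains away.
    Returns the updated state and the effective moisture (mm) available
    to drive production this month.
    """
    if params is None:
        params = GrassParams()
    if not math.isfinite(precip) or precip < 0:
        raise ValueError(f"precip must be finite and >= 0, got {precip}")
    capacity = bucket_capacity(soil)
    effective = (
        params.moisture_uptake_rain * precip
        + params.moisture_uptake_store * state.soil_water
    )
    residual = (
        (1.0 - params.moisture_uptake_rain) * precip
        + (1.0 - params.moisture_uptake_store) * state.soil_water
    )
    new_store = min(capacity, residual)  # excess drains
    return replace(state, soil_water=new_store), effective


def crude_protein(n_content: float) -> float:
    """Crude protein fraction from nitrogen content (× 6.25)."""
    if n_content < 0:
        raise ValueError("nitrogen content must be non-negative")
    return N_TO_PROTEIN * n_content


def live_digestibility(live_n: float, params: GrassParams) -> float:
    """Digestibility of live forage, linear in shoot nitrogen.

    Declines from ``digest_live_max`` at ``n_live_max`` down to
    ``digest_dead`` at ``n_live_min`` (quality of exhausted live tissue
    approaches that of standing dead).
    """
    span = params.n_live_max - params.n_live_min
    if span <= 0:
        return params.digest_live_max
    frac = (live_n - params.n_live_min) / span
    frac = min(1.0, max(0.0, frac))
    return params.digest_dead + frac * (params.digest_live_max - params.digest_dead)


def temperature_scalar(temp: float, params: GrassParams) -> float:
    """Smooth unimodal temperature limitation on production, in (0, 1]."""
    z = (temp - params.temp_opt) / params.temp_width
    return math.exp(-z * z)


@dataclass(frozen=True)
class GrowthFluxes:
    """Book-keeping of one month's mass fluxes (kg DM/ha)."""

    production: float
    to_shoot: float
    to_root: float
    senescence: float
    dead_decay: float
    root_turnover: float
    effective_moisture: float


def step_growth(
    state: ForageState,
    precip: float,
    temp: float,
    soil: SoilProfile,
    params: GrassParams,
    return_fluxes: bool = False,
) -> ForageState | tuple[ForageState, GrowthFluxes]:
    """Advance the forage state by one month (growth only, no offtake).

    production = rue × effective_moisture × temp_scalar × graze_penalty
    with graze_penalty = max(0, 1 − α·last_graze_intensity).  Production
    is split between shoot and root by a root:shoot ratio shifted toward
    roots by β·last_graze_intensity.  Senescence moves a fixed fraction
    of live biomass to the standing-dead pool, which itself decays.
    Shoot nitrogen is the mix of old tissue (relaxing toward its
    minimum) and new growth (at its maximum), raised by
    γ·last_graze_intensity and clipped to bounds.
    """
    if not (math.isfinite(precip) and math.isfinite(temp)):
        raise ValueError("climate inputs must be finite")
    state, eff = water_balance(state, precip, soil, params)

    penalty = max(0.0, 1.0 - params.graze_prod_penalty * state.last_graze_intensity)
    production = params.rue * eff * temperature_scalar(temp, params) * penalty

    rs = params.root_shoot_target * (
        1.0 + params.graze_rootshoot_shift * state.last_graze_intensity
    )
    shoot_frac = 1.0 / (1.0 + rs)
    to_shoot = production * shoot_frac
    to_root = production - to_shoot

    senescence = params.senescence_rate * state.live_biomass
    dead_decay = params.dead_decay_rate * state.dead_biomass
    root_turnover = params.root_turnover_rate * state.root_biomass

    new_live = state.live_biomass - senescence + to_shoot
    new_dead = state.dead_biomass + senescence - dead_decay
    new_root = state.root_biomass - root_turnover + to_root

    # shoot N: old tissue relaxes toward the minimum, new growth enters
    # at the maximum; grazing boosts quality (compensatory regrowth)
    n_old = params.n_live_min + (state.live_n - params.n_live_min) * (
        1.0 - params.n_decline_rate
    )
    old_live = state.live_biomass - senescence
    if old_live + to_shoot > 0:
        n_mix = (old_live * n_old + to_shoot * params.n_live_max) / (
            old_live + to_shoot
        )
    else:
        n_mix = n_old
    n_new = n_mix * (1.0 + params.graze_n_boost * state.last_graze_intensity)
    n_new = min(params.n_live_max, max(params.n_live_min, n_new))

    out = replace(
        state,
        live_biomass=max(0.0, new_live),
        dead_biomass=max(0.0, new_dead),
        root_biomass=max(0.0, new_root),
        live_n=n_new,
        dead_n=params.dead_n,
        last_graze_intensity=0.0,  # consumed; the coupler resets it after offtake
    )
    if return_fluxes:
        return out, GrowthFluxes(
            production=production,
            to_shoot=to_shoot,
            to_root=to_root,
            senescence=senescence,
            dead_decay=dead_decay,
            root_turnover=root_turnover,
            effective_moisture=eff,
        )
    return out


@dataclass
class SpinUpResult:
    state: ForageState
    years: int
    converged: bool
    peak_history: list[float] = field(default_factory=list)


def spin_up(
    climatology: ClimateSeries,
    soil: SoilProfile,
    params: GrassParams,
    schedule=None,
    threshold: float = 0.0,
    rel_tol: float = 1e-3,
    max_years: int = 100,
    initial: ForageState | None = None,
) -> SpinUpResult:
    """Equilibrate the forage state under a repeated climatological year.

    The 12-month climatology is repeated until the annual peak live
    biomass changes by less than ``rel_tol`` (relative) between
    successive years, or ``max_years`` is reached (a warning is issued
    and the last state returned, flagged as non-converged).  If a
    grazing ``schedule`` is given (mapping month-of-year 1-12 ->
    intensity fraction), scheduled offtake is applied each month with
    residual standing biomass kept at or above ``threshold``.
    Deterministic.
    """
    if len(climatology) != 12:
        raise ValueError("spin-up climatology must cover exactly 12 months")
    state = initial if initial is not None else ForageState(
        live_biomass=100.0, dead_biomass=50.0, root_biomass=100.0,
        live_n=params.n_live_max, dead_n=params.dead_n,
    )
    intensities = dict(schedule) if schedule else {}
    prev_peak: float | None = None
    history: list[float] = []
    for year in range(1, max_years + 1):
        peak = 0.0
        for i in range(12):
            month_of_year = climatology.months[i][1]
            state = step_growth(
                state, climatology.precip[i], climatology.temp_mean[i],
                soil, params,
            )
            inten = intensities.get(month_of_year, 0.0)
            if inten > 0.0:
                state = apply_offtake(state, inten * state.standing_biomass,
                                      threshold=threshold)
            peak = max(peak, state.live_biomass)
        history.append(peak)
        if prev_peak is not None:
            denom = max(prev_peak, 1e-9)
            if abs(peak - prev_peak) / denom < rel_tol:
                return SpinUpResult(state, year, True, history)
        prev_peak = peak
    warnings.warn(
        f"spin-up did not converge within {max_years} years "
        f"(last annual peak {prev_peak:.3f} kg/ha)",
        RuntimeWarning,
        stacklevel=2,
    )
    return SpinUpResult(state, max_years, False, history)


def apply_offtake(
    state: ForageState,
    demanded: float,
    threshold: float = 0.0,
) -> ForageState:
    """Remove ``demanded`` kg/ha of standing biomass, proportionally
    across the live and dead pools, never leaving less than
    ``threshold`` standing.  Records the realized removal fraction as
    ``last_graze_intensity`` for next month's grazing feedbacks.
    """
    if demanded < 0:
        raise ValueError("offtake demand must be non-negative")
    standing = state.standing_biomass
    if standing <= 0 or demanded == 0:
        return state
    allowed = max(0.0, standing - threshold)
    realized = min(demanded, allowed)
    frac = realized / standing
    return replace(
        state,
        live_biomass=state.live_biomass * (1.0 - frac),
        dead_biomass=state.dead_biomass * (1.0 - frac),
        last_graze_intensity=min(1.0, frac),
    )
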