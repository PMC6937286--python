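"""Maximum viable stocking density and the wild-grazer habitat index.

The maximum viable density of a site is the largest stocking density at
which the simulated herd experiences no more than a tolerated number of
diet-insufficient months (default 1) over a 24-month run.  The number
of insufficient months is non-decreasing in density, so the search is a
bisection on the density grid, equivalent to exhaustive search.

The viable-wild-grazer index is the forage surplus left for wildlife,
expressed in cattle-density units: maximum viable density minus the
reported (actual) cattle density, and as the proportion
1 − reported/maximum of the site's capacity left unused by livestock.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coupler import ManagementThreshold, months_insufficient, run_simulation
from .forage import ClimateSeries, ForageState, GrassParams, SoilProfile, spin_up
from .ruminant import HerdConfig, IntakeParams
from .scenarios import PrecipYear, scale_total

__all__ = [
    "ViabilityConfig",
    "WildGrazerIndex",
    "ViabilitySearchResult",
    "max_viable_density",
    "wild_grazer_index",
    "scenario_comparison",
]


@dataclass(frozen=True)
class ViabilityConfig:
    horizon_months: int = 24
    tolerated_insufficient_months: int = 1
    density_lo: float = 0.0  # animals/ha
    density_hi: float = 2.0
    density_resolution: float = 0.01

    def __post_init__(self) -> None:
        if self.horizon_months < 1:
            raise ValueError("horizon must be >= 1 month")
        if not self.density_lo < self.density_hi:
            raise ValueError("require density_lo < density_hi")
        if self.density_resolution <= 0:
            raise ValueError("density_resolution must be positive")


@dataclass(frozen=True)
class WildGrazerIndex:
    max_viable_density: float  # animals/ha
    reported_density: float
    viable_wild_density: float  # = max - reported
    proportion_for_wildlife: float | None  # = 1 - reported/max
    overstocked: bool  # reported exceeds the estimated maximum


@dataclass(frozen=True)
class ViabilitySearchResult:
    density: float  # animals/ha
    months_insufficient: int  # at the returned density
    evaluations: int
    flag: str | None  # None | not_viable_at_lower_bound | viable_at_upper_bound


def _climate_for_year(year: PrecipYear, temp: tuple[float, ...],
                      n_months: int, start_year: int = 2000) -> ClimateSeries:
    months, precip, temps = [], [], []
    y, m = start_year, 1
    for _ in range(n_months):
        months.append((y, m))
        precip.append(year.p[m - 1])
        temps.append(temp[m - 1])
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return ClimateSeries(tuple(months), tuple(precip), tuple(temps))


def max_viable_density(
    climate: ClimateSeries,
    soil: SoilProfile,
    grass: GrassParams,
    herd: HerdConfig,
    threshold: ManagementThreshold = ManagementThreshold(),
    cfg: ViabilityConfig = ViabilityConfig(),
    intake_params: IntakeParams | None = None,
) -> ViabilitySearchResult:
    """Largest stocking density (to the configured resolution) with at
    most the tolerated number of diet-insufficient months.

    The site is spun up once (ungrazed repeated climatology) and every
    candidate density is simulated from that common equilibrated state
    over the horizon.  months_insufficient must be non-decreasing in
    density; the bisection asserts this on the densities it visits and
    raises if the assumption is violated.
    """
    cfg_n = cfg.horizon_months
    if len(climate) < cfg_n:
        raise ValueError("climate does not cover the viability horizon")
    clim_year = ClimateSeries(climate.months[:12], climate.precip[:12],
                              climate.temp_mean[:12])
    state0 = spin_up(clim_year, soil, grass).state

    evals: dict[int, int] = {}

    res = cfg.density_resolution
    n_steps = int(round((cfg.density_hi - cfg.density_lo) / res))

    def insufficient(i: int) -> int:
        if i not in evals:
            d = cfg.density_lo + i * res
            sim = run_simulation(
                climate, soil, grass, herd.with_density(d), threshold,
                months=cfg_n, do_spin_up=False, initial_state=state0,
                intake_params=intake_params,
            )
            evals[i] = months_insufficient(sim)
        return evals[i]

    def viable(i: int) -> bool:
        return insufficient(i) <= cfg.tolerated_insufficient_months

    if not viable(0):
        return ViabilitySearchResult(cfg.density_lo, insufficient(0),
                                     len(evals), "not_viable_at_lower_bound")
    if viable(n_steps):
        return ViabilitySearchResult(cfg.density_hi, insufficient(n_steps),
                                     len(evals), "viable_at_upper_bound")

    lo, hi = 0, n_steps  # invariant: viable(lo), not viable(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if viable(mid):
            lo = mid
        else:
            hi = mid
    # the search assumes months_insufficient is non-decreasing in
    # density; verify it on every density actually simulated
    visited = sorted(evals.items())
    for (_, a), (_, b) in zip(visited, visited[1:]):
        if b < a:
            raise RuntimeError(
                "months_insufficient decreased with stocking density; "
                "the bisection assumption is violated for this site"
            )
    return ViabilitySearchResult(cfg.density_lo + lo * res, insufficient(lo),
                                 len(evals), None)


def wild_grazer_index(max_viable: float, reported: float) -> WildGrazerIndex:
    """Forage surplus available to wild grazers, in cattle-density units."""
    if max_viable < 0 or reported < 0:
        raise ValueError("densities must be non-negative")
    viable_wild = max_viable - reported
    proportion = 1.0 - reported / max_viable if max_viable > 0 else None
    return WildGrazerIndex(
        max_viable_density=max_viable,
        reported_density=reported,
        viable_wild_density=viable_wild,
        proportion_for_wildlife=proportion,
        overstocked=viable_wild < 0,
    )


def scenario_comparison(
    base_year: PrecipYear,
    monthly_temp: tuple[float, ...],
    soil: SoilProfile,
    grass: GrassParams,
    herd: HerdConfig,
    reported_density: float,
    threshold: ManagementThreshold = ManagementThreshold(),
    cfg: ViabilityConfig = ViabilityConfig(),
    intake_params: IntakeParams | None = None,
    drought_factor: float = 0.4,
    wet_factor: float = 1.6,
    low_stocking: float = 0.07,
    high_stocking: float = 0.43,
) -> pd.DataFrame:
    """Wild-grazer habitat under climate and management extremes.

    Rows: baseline; extreme drought (total rainfall scaled to 40% of
    average, reported density unchanged); heavy rainfall (160%);
    wildlife-dominated management (reported density set to the lowest
    regional value, 0.07 cattle/ha, baseline climate); and
    livestock-dominated management (highest regional value, 0.43).
    Reports viable wild density and its percent change from baseline.
    """
    def mvd(year: PrecipYear) -> float:
        clim = _climate_for_year(year, monthly_temp, cfg.horizon_months)
        return max_viable_density(clim, soil, grass, herd, threshold, cfg,
                                  intake_params).density

    base_mvd = mvd(base_year)
    if base_mvd <= 0:
        raise ValueError(
            "baseline maximum viable density is zero; index undefined"
        )
    rows = [
        ("baseline", base_mvd, reported_density),
        ("drought", mvd(scale_total(base_year, drought_factor)),
         reported_density),
        ("wet", mvd(scale_total(base_year, wet_factor)), reported_density),
        ("low_stocking", base_mvd, low_stocking),
        ("high_stocking", base_mvd, high_stocking),
    ]
    base_wild = base_mvd - reported_density
    out = []
    for name, mv, rep in rows:
        idx = wild_grazer_index(mv, rep)
        pct = (
            100.0 * (idx.viable_wild_density - base_wild) / abs(base_wild)
            if base_wild != 0 else float("nan")
        )
        out.append({
            "scenario": name,
            "max_viable_density": mv,
            "reported_density": rep,
            "viable_wild_density": idx.viable_wild_density,
            "proportion_for_wildlife": idx.proportion_for_wildlife,
            "pct_change_vs_baseline": 0.0 if name == "baseline" else pct,
        })
    return pd.DataFrame(out)
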