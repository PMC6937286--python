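"""Synthetic semi-arid site generator.

Produces complete, internally consistent model inputs emulating an
East-African bimodal-rainfall rangeland (long rains around April, short
rains around November, annual totals of a few hundred mm, zebu-type
cattle herds, a 300 kg/ha residual-biomass management rule).  All
randomness lives here, keyed by an explicit seed; the simulator core is
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coupler import GrazingSchedule, ManagementThreshold
from .forage import ClimateSeries, GrassParams, SoilProfile
from .ruminant import AnimalClass, HerdConfig

__all__ = ["SyntheticSiteSpec", "SyntheticSite", "make_site",
           "make_true_schedule"]

_SOIL_PRESETS = {
    "sandy_loam": SoilProfile(sand_fraction=0.60, silt_fraction=0.25,
                              clay_fraction=0.15, bulk_density=1.45, ph=6.3),
    "clay_loam": SoilProfile(sand_fraction=0.30, silt_fraction=0.35,
                             clay_fraction=0.35, bulk_density=1.25, ph=6.8),
}


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Recipe for a synthetic site."""

    annual_precip_mm: float = 600.0
    peak_months: tuple[int, int] = (4, 11)  # long and short rains
    peak_sharpness: float = 1.5  # months, width of each rainy season
    mean_temp: float = 22.0  # degC
    temp_amplitude: float = 3.0  # degC seasonal swing
    soil_preset: str = "sandy_loam"
    stocking_density: float = 0.3  # animals/ha
    residual_threshold: float = 300.0  # kg/ha
    years: int = 4
    start_year: int = 2000
    precip_noise_cv: float = 0.0  # lognormal CV; 0 = noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_precip_mm <= 0:
            raise ValueError("annual precipitation must be positive")
        if any(not 1 <= m <= 12 for m in self.peak_months):
            raise ValueError("peak months must be in 1..12")
        if self.soil_preset not in _SOIL_PRESETS:
            raise ValueError(
                f"unknown soil preset {self.soil_preset!r}; "
                f"choose from {sorted(_SOIL_PRESETS)}"
            )
        if self.years < 1:
            raise ValueError("need at least one year")
        if self.peak_sharpness <= 0:
            raise ValueError("peak_sharpness must be positive")


@dataclass(frozen=True)
class SyntheticSite:
    climate: ClimateSeries
    soil: SoilProfile
    grass: GrassParams
    herd: HerdConfig
    threshold: ManagementThreshold
    monthly_precip_pattern: tuple[float, ...]  # noise-free one-year pattern
    monthly_temp_pattern: tuple[float, ...]


def _circular_distance(a: float, b: float, period: int = 12) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def _rain_pattern(spec: SyntheticSiteSpec) -> np.ndarray:
    """Noise-free monthly rainfall: two-Gaussian mixture over month of
    year, scaled to the annual total."""
    months = np.arange(1, 13, dtype=float)
    w = np.zeros(12)
    for peak in spec.peak_months:
        d = np.array([_circular_distance(m, peak) for m in months])
        w += np.exp(-((d / spec.peak_sharpness) ** 2))
    return w / w.sum() * spec.annual_precip_mm


def _default_herd(density: float) -> HerdConfig:
    """Zebu-type cattle herd: breeding cows with followers."""
    cow = AnimalClass(label="breeding_cow", sex="female", age_months=60,
                      weight=320.0, standard_ref_weight=350.0,
                      conception_month=6, calving_interval=15,
                      lactation_duration=6)
    heifer = AnimalClass(label="heifer", sex="female", age_months=20,
                         weight=200.0, standard_ref_weight=350.0)
    steer = AnimalClass(label="steer", sex="castrate", age_months=30,
                        weight=280.0, standard_ref_weight=380.0)
    return HerdConfig(
        classes=((cow, 0.5), (heifer, 0.25), (steer, 0.25)),
        stocking_density=density,
    )


def make_site(spec: SyntheticSiteSpec = SyntheticSiteSpec()) -> SyntheticSite:
    """Build a complete synthetic site from a spec.  Deterministic for a
    given seed."""
    rng = np.random.default_rng(spec.seed)
    pattern = _rain_pattern(spec)
    temps = np.array([
        spec.mean_temp + spec.temp_amplitude
        * math.cos(2 * math.pi * (m - 3) / 12.0)
        for m in range(1, 13)
    ])

    months, precip, temp = [], [], []
    for yr in range(spec.years):
        if spec.precip_noise_cv > 0:
            sigma = math.sqrt(math.log(1 + spec.precip_noise_cv ** 2))
            noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=12)
            year_precip = pattern * noise
        else:
            year_precip = pattern
        for m in range(12):
            months.append((spec.start_year + yr, m + 1))
            precip.append(float(year_precip[m]))
            temp.append(float(temps[m]))

    climate = ClimateSeries(tuple(months), tuple(precip), tuple(temp))
    return SyntheticSite(
        climate=climate,
        soil=_SOIL_PRESETS[spec.soil_preset],
        grass=GrassParams(),
        herd=_default_herd(spec.stocking_density),
        threshold=ManagementThreshold(spec.residual_threshold),
        monthly_precip_pattern=tuple(float(v) for v in pattern),
        monthly_temp_pattern=tuple(float(v) for v in temps),
    )


def make_true_schedule(
    seed: int,
    months: list[tuple[int, int]],
    event_probability: float = 0.5,
    intensity_range: tuple[float, float] = (0.05, 0.25),
) -> GrazingSchedule:
    """Random ground-truth grazing schedule for calibration-recovery
    tests: a random subset of the given months is grazed at intensities
    drawn uniformly from ``intensity_range``."""
    rng = np.random.default_rng(seed)
    events = {}
    for ym in months:
        if rng.random() < event_probability:
            events[ym] = float(rng.uniform(*intensity_range))
    return GrazingSchedule(events)
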