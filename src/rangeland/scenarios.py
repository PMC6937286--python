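"""Precipitation scenario engine.

Intra-annual rainfall concentration is summarized by the precipitation
concentration index,

    PCI = 100 × Σ pᵢ² / (Σ pᵢ)²,

over the 12 monthly totals pᵢ: 100/12 ≈ 8.33 for perfectly uniform
rain, 100 when all rain falls in a single month.  Scenarios rescale a
base year's total (PCI-invariant) and redistribute rain between months
to hit a target PCI at fixed total, supporting a factorial grid of
total × concentration levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PrecipYear",
    "Scenario",
    "ScenarioGrid",
    "PCI_FLOOR",
    "pci",
    "classify_pci",
    "scale_total",
    "adjust_pci",
    "generate_grid",
    "DEFAULT_FACTORS",
]

#: Minimum possible PCI over 12 months (perfectly uniform rainfall).
PCI_FLOOR = 100.0 / 12.0

#: The six factor levels used for both total precipitation and PCI
#: manipulation: 20% to 120% of the empirical value.
DEFAULT_FACTORS = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)


@dataclass(frozen=True)
class PrecipYear:
    """Twelve monthly precipitation totals, mm."""

    p: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.p) != 12:
            raise ValueError("a precipitation year has 12 monthly values")
        if any(v < 0 or not np.isfinite(v) for v in self.p):
            raise ValueError("monthly precipitation must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.p))

    @classmethod
    def from_values(cls, values) -> "PrecipYear":
        return cls(tuple(float(v) for v in values))


@dataclass(frozen=True)
class Scenario:
    total_factor: float
    pci_factor: float
    year: PrecipYear
    realized_total: float
    realized_pci: float


@dataclass(frozen=True)
class ScenarioGrid:
    scenarios: tuple[Scenario, ...]

    def __len__(self) -> int:
        return len(self.scenarios)


def pci(year: PrecipYear) -> float:
    """Precipitation concentration index of a 12-month year."""
    p = np.asarray(year.p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("PCI is undefined for an all-zero year")
    return float(100.0 * (p ** 2).sum() / total ** 2)


def classify_pci(value: float) -> str:
    """Qualitative rainfall-distribution class for a PCI value.

    < 11 uniform; [11, 16) moderate; [16, 20] irregular; > 20 strongly
    irregular.
    """
    if value < 0:
        raise ValueError("PCI must be non-negative")
    if value < 11.0:
        return "uniform"
    if value < 16.0:
        return "moderate"
    if value <= 20.0:
        return "irregular"
    return "strongly_irregular"


def scale_total(year: PrecipYear, factor: float) -> PrecipYear:
    """Multiply every month by ``factor`` (> 0); PCI is unchanged."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return PrecipYear.from_values(v * factor for v in year.p)


def _pci_of_gamma(p: np.ndarray, gamma: float) -> float:
    """PCI after the power transform p_i -> p_i**gamma (total-rescaled;
    PCI is scale-invariant so the rescale can be skipped here)."""
    with np.errstate(over="ignore"):
        q = np.power(p, gamma)
    if not np.all(np.isfinite(q)):
        # normalize before powering to avoid overflow at large gamma
        q = np.power(p / p.max(), gamma)
    s = q.sum()
    return float(100.0 * (q ** 2).sum() / s ** 2)


def adjust_pci(year: PrecipYear, target_pci: float,
               tol: float = 1e-6) -> PrecipYear:
    """Redistribute rain between months to reach ``target_pci`` while
    preserving the annual total.

    Implemented as the power transform pᵢ′ ∝ pᵢ^γ rescaled to the
    original total; γ > 1 concentrates rain into wetter months (raising
    PCI), γ < 1 flattens the year (lowering it).  γ is found by 1-D
    root search.  Targets below the 12-month floor 100/12 are clamped
    to the floor with a warning.  Targets unreachable by the transform
    (e.g. below the floor implied by the year's zero months, or above
    what concentration into the wettest month can deliver) raise a
    ValueError with a diagnostic.
    """
    p = np.asarray(year.p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot adjust an all-zero year")
    if target_pci < PCI_FLOOR:
        warnings.warn(
            f"target PCI {target_pci:.3f} below the 12-month floor "
            f"{PCI_FLOOR:.3f}; clamping to the floor",
            RuntimeWarning,
            stacklevel=2,
        )
        target_pci = PCI_FLOOR
    if target_pci > 100.0:
        raise ValueError("target PCI cannot exceed 100")

    current = pci(year)
    if abs(current - target_pci) <= tol:
        return year

    lo, hi = 1e-6, 1.0
    if target_pci > current:
        lo, hi = 1.0, 2.0
        # PCI(gamma) is increasing; widen until the target is bracketed
        while _pci_of_gamma(p, hi) < target_pci:
            hi *= 2.0
            if hi > 4096.0:
                raise ValueError(
                    f"target PCI {target_pci:.3f} not reachable by "
                    f"concentration (limit {_pci_of_gamma(p, hi):.3f} "
                    "set by ties among the wettest months)"
                )
    else:
        reachable_floor = _pci_of_gamma(p, lo)
        if target_pci <= reachable_floor + 1e-3:
            if reachable_floor > target_pci + 1e-3:
                # floor set by the year's zero-rain months: flattening
                # cannot move rain into a month that has none
                raise ValueError(
                    f"target PCI {target_pci:.3f} below the reachable "
                    f"floor {reachable_floor:.3f} (zero-rain months fix it)"
                )
            # target sits on the flat-year floor itself
            q = np.power(p / p.max(), lo)
            q *= total / q.sum()
            return PrecipYear.from_values(q)

    gamma = brentq(lambda g: _pci_of_gamma(p, g) - target_pci, lo, hi,
                   xtol=1e-12, rtol=8.9e-16)
    q = np.power(p / p.max(), gamma)
    q *= total / q.sum()
    return PrecipYear.from_values(q)


def generate_grid(
    year: PrecipYear,
    total_factors=DEFAULT_FACTORS,
    pci_factors=DEFAULT_FACTORS,
) -> ScenarioGrid:
    """Factorial grid of total-precipitation × PCI manipulations.

    For each (total factor, PCI factor) pair the base year is first
    redistributed to PCI = factor × empirical PCI (clamped at the
    uniform floor) and then rescaled so its total is factor × empirical
    total.  The default 6 × 6 levels give 36 scenarios.
    """
    if not total_factors or not pci_factors:
        raise ValueError("factor lists must be non-empty")
    if any(f <= 0 for f in total_factors) or any(f <= 0 for f in pci_factors):
        raise ValueError("factors must be positive")
    base_pci = pci(year)
    scenarios = []
    for tf in total_factors:
        for pf in pci_factors:
            target = pf * base_pci
            with warnings.catch_warnings():
                if target < PCI_FLOOR:
                    warnings.simplefilter("ignore", RuntimeWarning)
                redistributed = adjust_pci(year, max(target, PCI_FLOOR))
            scaled = scale_total(redistributed, tf)
            scenarios.append(Scenario(
                total_factor=tf,
                pci_factor=pf,
                year=scaled,
                realized_total=scaled.total,
                realized_pci=pci(scaled),
            ))
    return ScenarioGrid(tuple(scenarios))
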