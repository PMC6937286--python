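"""Back-calculation of grazing management from a biomass measurement.

Grazing history is rarely recorded, but a single standing-biomass
measurement constrains it: given a site's climate and soil, the routine
iteratively modifies a scheduled grazing history — first by adding or
removing grazing events in the months preceding the measurement, then
by adjusting event intensity — until the simulated standing biomass at
the measurement date matches the observation within tolerance.

Fit improvement from default to calibrated schedules is summarized by
the change in mean squared error of prediction,

    ΔMSEP = mean_i[(O_i − P_i,default)² − (O_i − P_i,calibrated)²],

positive when calibration improved the fit, and by the mean bias,

    MB = mean_i(O_i − P_i,calibrated),

negative when the calibrated model overestimates biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coupler import (
    GrazingSchedule,
    ManagementThreshold,
    SimulationResult,
    run_scheduled,
)
from .forage import ClimateSeries, GrassParams, SoilProfile

__all__ = [
    "BiomassTarget",
    "CalibrationConfig",
    "FitMetrics",
    "CalibrationTrace",
    "back_calculate",
    "delta_msep",
    "mean_bias",
    "grazing_intensity_summary",
]


@dataclass(frozen=True)
class BiomassTarget:
    """An empirical total standing biomass observation (kg DM/ha)."""

    year: int
    month: int
    biomass: float

    def __post_init__(self) -> None:
        if self.biomass <= 0:
            raise ValueError("target biomass must be positive")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")


@dataclass(frozen=True)
class CalibrationConfig:
    mode: str = "both"  # schedule_only | intensity_only | both
    window_months: int = 24
    intensity_step: float = 0.05
    default_event_intensity: float = 0.1
    tolerance_abs: float = 10.0  # kg/ha
    tolerance_rel: float = 0.01
    max_iterations: int = 40

    def __post_init__(self) -> None:
        if self.mode not in ("schedule_only", "intensity_only", "both"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.window_months < 1:
            raise ValueError("window_months must be >= 1")
        if self.intensity_step <= 0 or self.tolerance_abs <= 0:
            raise ValueError("steps and tolerances must be positive")
        if self.tolerance_rel <= 0 or self.max_iterations < 1:
            raise ValueError("steps and tolerances must be positive")

    def tolerance(self, target: float) -> float:
        return max(self.tolerance_abs, self.tolerance_rel * target)


@dataclass(frozen=True)
class FitMetrics:
    delta_msep: float  # kg^2/ha^2
    mean_bias: float  # kg/ha


@dataclass
class CalibrationTrace:
    iterations: list[dict] = field(default_factory=list)
    converged: bool = False
    message: str = ""

    def record(self, action: str, simulated: float, error: float) -> None:
        self.iterations.append({
            "iteration": len(self.iterations) + 1,
            "action": action,
            "simulated_biomass": simulated,
            "error": error,
        })

    def __len__(self) -> int:
        return len(self.iterations)


def delta_msep(
    observed: Sequence[float],
    pred_default: Sequence[float],
    pred_calibrated: Sequence[float],
) -> float:
    """Improvement in mean squared error of prediction (kg²/ha²)."""
    o = np.asarray(observed, dtype=float)
    pd_ = np.asarray(pred_default, dtype=float)
    pc = np.asarray(pred_calibrated, dtype=float)
    if not (o.shape == pd_.shape == pc.shape) or o.ndim != 1 or o.size < 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    return float(np.mean((o - pd_) ** 2 - (o - pc) ** 2))


def mean_bias(observed: Sequence[float],
              pred_calibrated: Sequence[float]) -> float:
    """Mean of observed − predicted (kg/ha); negative = overestimation."""
    o = np.asarray(observed, dtype=float)
    pc = np.asarray(pred_calibrated, dtype=float)
    if o.shape != pc.shape or o.ndim != 1 or o.size < 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    return float(np.mean(o - pc))


def _window_months(target: BiomassTarget, window: int) -> list[tuple[int, int]]:
    """The ``window`` calendar months up to and including the target
    date, nearest first."""
    out = []
    y, m = target.year, target.month
    for _ in range(window):
        out.append((y, m))
        m -= 1
        if m == 0:
            y, m = y - 1, 12
    return out


def _simulate_at(
    climate: ClimateSeries,
    soil: SoilProfile,
    grass: GrassParams,
    schedule: GrazingSchedule,
    target: BiomassTarget,
    threshold: ManagementThreshold,
) -> float:
    idx = climate.index_of(target.year, target.month)
    result = run_scheduled(climate, soil, grass, schedule,
                           months=idx + 1, threshold=threshold)
    return result.standing_biomass(target.year, target.month)


def back_calculate(
    climate: ClimateSeries,
    soil: SoilProfile,
    grass: GrassParams,
    start_schedule: GrazingSchedule,
    target: BiomassTarget,
    cfg: CalibrationConfig = CalibrationConfig(),
    threshold: ManagementThreshold = ManagementThreshold(0.0),
) -> tuple[GrazingSchedule, CalibrationTrace]:
    """Calibrate a grazing schedule to one biomass observation.

    Simulated biomass above the target calls for more grazing: events
    are added in ungrazed months within the window, nearest to the
    measurement date first; once every window month carries an event,
    intensity is raised uniformly by ``intensity_step`` until the
    target is bracketed and then refined by bisection.  Simulated
    biomass below the target mirrors this (events removed farthest
    first, intensity lowered).  ``schedule_only`` and ``intensity_only``
    modes restrict the available levers.  Returns the calibrated
    schedule and a per-iteration trace (flagged non-converged if the
    tolerance was not reached within ``max_iterations``).
    """
    try:
        climate.index_of(target.year, target.month)
    except KeyError:
        raise ValueError(
            f"target date ({target.year}, {target.month}) outside the "
            "simulated span"
        ) from None
    if cfg.mode == "intensity_only" and not start_schedule.grazed_months():
        raise ValueError(
            "intensity_only mode requires a start schedule with events"
        )

    window = _window_months(target, cfg.window_months)
    in_window = set(window)
    tol = cfg.tolerance(target.biomass)
    trace = CalibrationTrace()
    schedule = start_schedule.copy()

    def sim(s: GrazingSchedule) -> float:
        return _simulate_at(climate, soil, grass, s, target, threshold)

    def with_uniform(u: float) -> GrazingSchedule:
        s = schedule.copy()
        for key in s.events:
            if key in in_window:
                s.events[key] = min(1.0, max(0.0, u))
        return s

    current = sim(schedule)
    trace.record("initial", current, current - target.biomass)
    if abs(current - target.biomass) <= tol:
        trace.converged = True
        trace.message = "already within tolerance"
        return schedule, trace

    allow_schedule = cfg.mode in ("schedule_only", "both")
    allow_intensity = cfg.mode in ("intensity_only", "both")

    # Phase 1: add/remove events.  prev tracks the last simulated value
    # so a sign change (target crossed) hands over to the intensity
    # phase with a bracket already in hand.
    if allow_schedule:
        while len(trace) < cfg.max_iterations:
            err = current - target.biomass
            if abs(err) <= tol:
                trace.converged = True
                return schedule, trace
            if err > 0:  # too much biomass: graze more
                slot = next((ym for ym in window
                             if schedule.events.get(ym, 0.0) == 0.0
                             and ym in set(climate.months)), None)
                if slot is None:
                    break  # window saturated -> intensity lever
                schedule.events[slot] = cfg.default_event_intensity
                action = f"add_event {slot}"
            else:  # too little biomass: graze less
                grazed = [ym for ym in reversed(window)
                          if schedule.events.get(ym, 0.0) > 0.0]
                if not grazed:
                    trace.message = (
                        "target above ungrazed biomass; no upward lever"
                    )
                    return schedule, trace
                removed = grazed[0]
                del schedule.events[removed]
                action = f"remove_event {removed}"
            prev = current
            current = sim(schedule)
            trace.record(action, current, current - target.biomass)
            # crossing the target means a bracket exists; intensity
            # refinement is strictly better than thrashing add/remove
            if allow_intensity and (prev - target.biomass) * (
                    current - target.biomass) < 0:
                break

    # Phase 2: uniform intensity on window events, stepped then bisected.
    if allow_intensity and len(trace) < cfg.max_iterations:
        window_events = [k for k in schedule.events if k in in_window]
        if window_events:
            u = float(np.mean([schedule.events[k] for k in window_events]))
            schedule = with_uniform(u)
            current = sim(schedule)
            trace.record(f"uniform_intensity {u:.4f}", current,
                         current - target.biomass)
            err = current - target.biomass
            lo = hi = None  # lo: intensity giving sim above target
            if err > 0:
                lo = u
            else:
                hi = u
            step = cfg.intensity_step
            while len(trace) < cfg.max_iterations:
                if abs(current - target.biomass) <= tol:
                    trace.converged = True
                    return schedule, trace
                if lo is not None and hi is not None:
                    u = 0.5 * (lo + hi)
                    action = f"bisect_intensity {u:.4f}"
                elif lo is not None:  # still above target: graze harder
                    if u >= 1.0:
                        trace.message = "intensity saturated at 1.0"
                        return schedule, trace
                    u = min(1.0, u + step)
                    action = f"step_intensity_up {u:.4f}"
                else:  # below target: graze lighter
                    if u <= 0.0:
                        trace.message = (
                            "target above ungrazed biomass; no upward lever"
                        )
                        return schedule, trace
                    u = max(0.0, u - step)
                    action = f"step_intensity_down {u:.4f}"
                schedule = with_uniform(u)
                current = sim(schedule)
                trace.record(action, current, current - target.biomass)
                if current > target.biomass:
                    lo = u
                else:
                    hi = u

    err = current - target.biomass
    if abs(err) <= tol:
        trace.converged = True
    else:
        trace.message = trace.message or (
            f"not converged after {len(trace)} iterations "
            f"(residual {err:.1f} kg/ha)"
        )
    return schedule, trace


def grazing_intensity_summary(
    result: SimulationResult,
    end_year: int,
    end_month: int,
    lookback: int = 12,
) -> tuple[float, float]:
    """Average monthly offtake over the ``lookback`` months ending at the
    given date: (kg/ha/month, percent of standing biomass removed).
    """
    idx = None
    for i, r in enumerate(result.records):
        if (r.year, r.month) == (end_year, end_month):
            idx = i
            break
    if idx is None or idx + 1 < lookback:
        raise ValueError(
            f"result does not cover {lookback} months ending at "
            f"({end_year}, {end_month})"
        )
    recs = result.records[idx + 1 - lookback: idx + 1]
    offtakes = [r.offtake for r in recs]
    # percent of pre-offtake standing biomass removed each month
    pcts = []
    for r in recs:
        standing_before = r.live_biomass + r.dead_biomass + r.offtake
        pcts.append(100.0 * r.offtake / standing_before
                    if standing_before > 0 else 0.0)
    return float(np.mean(offtakes)), float(np.mean(pcts))
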