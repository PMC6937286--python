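"""Model/Results front end.

:class:`RangelandModel` bundles a site's climate, soil, grass and herd
description the way statistical packages bundle endog/exog, exposes the
coupled simulation directly, and — because the back-calculate routine is
a fit of a grazing schedule to an observed biomass — exposes the
calibration as ``fit()`` returning a :class:`CalibrationResults` with
the calibrated schedule, fit metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .backcalc import (
    BiomassTarget,
    CalibrationConfig,
    CalibrationTrace,
    FitMetrics,
    back_calculate,
    delta_msep,
    grazing_intensity_summary,
    mean_bias,
)
from .coupler import (
    GrazingSchedule,
    ManagementThreshold,
    SimulationResult,
    months_insufficient,
    run_scheduled,
    run_simulation,
)
from .forage import ClimateSeries, GrassParams, SoilProfile
from .ruminant import HerdConfig, IntakeParams
from .viability import ViabilityConfig, ViabilitySearchResult, max_viable_density

__all__ = ["RangelandModel", "CalibrationResults"]


@dataclass
class RangelandModel:
    """A site: climate forcing plus soil, grass, herd and management.

    Entry points: :meth:`simulate` (herd-driven run),
    :meth:`simulate_scheduled` (prescribed grazing events),
    :meth:`fit` (back-calculate a schedule from one biomass
    observation) and :meth:`max_viable_density`.
    """

    climate: ClimateSeries
    soil: SoilProfile
    grass: GrassParams = field(default_factory=GrassParams)
    herd: HerdConfig | None = None
    threshold: ManagementThreshold = field(
        default_factory=ManagementThreshold)
    intake_params: IntakeParams = field(default_factory=IntakeParams)

    @classmethod
    def from_site(cls, site) -> "RangelandModel":
        """Build from a :class:`~rangeland.fixtures.SyntheticSite` (or
        any object with climate/soil/grass/herd/threshold attributes)."""
        return cls(climate=site.climate, soil=site.soil, grass=site.grass,
                   herd=site.herd, threshold=site.threshold)

    def simulate(self, months: int | None = None,
                 stocking_density: float | None = None,
                 do_spin_up: bool = True) -> SimulationResult:
        if self.herd is None:
            raise ValueError("herd-driven simulation needs a herd")
        herd = (self.herd if stocking_density is None
                else self.herd.with_density(stocking_density))
        return run_simulation(
            self.climate, self.soil, self.grass, herd, self.threshold,
            months=months, do_spin_up=do_spin_up,
            intake_params=self.intake_params,
        )

    def simulate_scheduled(self, schedule: GrazingSchedule,
                           months: int | None = None,
                           do_spin_up: bool = True) -> SimulationResult:
        return run_scheduled(
            self.climate, self.soil, self.grass, schedule,
            months=months, threshold=self.threshold,
            do_spin_up=do_spin_up,
        )

    def fit(self, target: BiomassTarget,
            start_schedule: GrazingSchedule | None = None,
            config: CalibrationConfig = CalibrationConfig(),
            ) -> "CalibrationResults":
        """Back-calculate the grazing schedule that reproduces the
        observed biomass at the target date."""
        start = start_schedule or GrazingSchedule()
        default_sim = self.simulate_scheduled(start)
        pred_default = default_sim.standing_biomass(target.year, target.month)
        schedule, trace = back_calculate(
            self.climate, self.soil, self.grass, start, target, config,
            threshold=self.threshold,
        )
        calib_sim = self.simulate_scheduled(schedule)
        pred_calib = calib_sim.standing_biomass(target.year, target.month)
        metrics = FitMetrics(
            delta_msep=delta_msep([target.biomass], [pred_default],
                                  [pred_calib]),
            mean_bias=mean_bias([target.biomass], [pred_calib]),
        )
        return CalibrationResults(
            model=self, target=target, schedule=schedule, trace=trace,
            pred_default=pred_default, pred_calibrated=pred_calib,
            metrics=metrics, result=calib_sim,
        )

    def max_viable_density(
            self, cfg: ViabilityConfig = ViabilityConfig()
    ) -> ViabilitySearchResult:
        if self.herd is None:
            raise ValueError("viability search needs a herd")
        return max_viable_density(
            self.climate, self.soil, self.grass, self.herd, self.threshold,
            cfg, self.intake_params,
        )

    def months_insufficient(self, months: int | None = None,
                            stocking_density: float | None = None) -> int:
        return months_insufficient(
            self.simulate(months=months, stocking_density=stocking_density))


@dataclass
class CalibrationResults:
    """Outcome of fitting a grazing schedule to a biomass observation."""

    model: RangelandModel
    target: BiomassTarget
    schedule: GrazingSchedule
    trace: CalibrationTrace
    pred_default: float  # kg/ha at target date, starting schedule
    pred_calibrated: float  # kg/ha at target date, calibrated schedule
    metrics: FitMetrics
    result: SimulationResult  # full run under the calibrated schedule

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    def recent_grazing(self, lookback: int = 12) -> tuple[float, float]:
        """Mean monthly offtake (kg/ha) and percent of standing biomass
        removed over the ``lookback`` months before the measurement."""
        return grazing_intensity_summary(
            self.result, self.target.year, self.target.month, lookback)

    def summary(self) -> str:
        off_kg, off_pct = self.recent_grazing()
        lines = [
            "Back-calculated grazing management",
            "==================================",
            f"Target biomass            {self.target.biomass:10.1f} kg/ha "
            f"at ({self.target.year}, {self.target.month:02d})",
            f"Simulated (default)       {self.pred_default:10.1f} kg/ha",
            f"Simulated (calibrated)    {self.pred_calibrated:10.1f} kg/ha",
            f"Converged                 {str(self.converged):>10s} "
            f"in {self.n_iterations} iterations",
            f"Grazing events in schedule{len(self.schedule.grazed_months()):>11d}",
            f"dMSEP                     {self.metrics.delta_msep:10.1f} kg^2/ha^2",
            f"Mean bias                 {self.metrics.mean_bias:10.2f} kg/ha",
            f"Mean offtake (12 mo)      {off_kg:10.1f} kg/ha/month "
            f"({off_pct:.1f}% of standing)",
        ]
        if self.trace.message:
            lines.append(f"Note: {self.trace.message}")
        return "\n".join(lines)
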