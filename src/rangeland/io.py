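"""File readers and writers.

Climate and grazing-schedule data travel as plain CSV; soil, grass and
herd parameters as flat YAML key-value files whose keys are exactly the
dataclass field names.  Every writer produces files its reader accepts
round-trip.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .coupler import GrazingSchedule, SimulationResult
from .forage import ClimateSeries, GrassParams, SoilProfile
from .ruminant import AnimalClass, HerdConfig

__all__ = [
    "read_climate", "write_climate",
    "read_soil", "write_soil",
    "read_grass", "write_grass",
    "read_herd", "write_herd",
    "read_schedule", "write_schedule",
    "write_result",
]

_CLIMATE_COLS = ["year", "month", "precip_mm", "temp_c"]


class ParseError(ValueError):
    """Input file failed schema validation."""


def read_climate(path: str | Path) -> ClimateSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CLIMATE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if not 1 <= row["month"] <= 12:
            raise ParseError(
                f"{path}: row {i + 2}: month {row['month']} out of 1..12"
            )
        if row["precip_mm"] < 0:
            raise ParseError(
                f"{path}: row {i + 2}: negative precipitation"
            )
    try:
        return ClimateSeries.from_columns(
            df["year"], df["month"], df["precip_mm"], df["temp_c"]
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_climate(series: ClimateSeries, path: str | Path) -> None:
    pd.DataFrame({
        "year": [y for y, _ in series.months],
        "month": [m for _, m in series.months],
        "precip_mm": series.precip,
        "temp_c": series.temp_mean,
    }).to_csv(path, index=False)


def _read_kv(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a flat key-value mapping")
    return data


def read_soil(path: str | Path) -> SoilProfile:
    try:
        return SoilProfile(**_read_kv(path))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_soil(soil: SoilProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(soil), fh, sort_keys=False)


def read_grass(path: str | Path) -> GrassParams:
    try:
        return GrassParams(**_read_kv(path))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_grass(grass: GrassParams, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(grass), fh, sort_keys=False)


def read_herd(path: str | Path) -> HerdConfig:
    data = _read_kv(path)
    try:
        classes = tuple(
            (AnimalClass(**{k: v for k, v in entry.items()
                            if k != "proportion"}),
             float(entry["proportion"]))
            for entry in data["classes"]
        )
        return HerdConfig(classes=classes,
                          stocking_density=float(data["stocking_density"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_herd(herd: HerdConfig, path: str | Path) -> None:
    data = {
        "stocking_density": herd.stocking_density,
        "classes": [
            {**asdict(animal), "proportion": prop}
            for animal, prop in herd.classes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_schedule(path: str | Path) -> GrazingSchedule:
    df = pd.read_csv(path)
    needed = ["year", "month", "grazing_flag", "intensity"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    events = {}
    for i, row in df.iterrows():
        if not 1 <= row["month"] <= 12:
            raise ParseError(
                f"{path}: row {i + 2}: month {row['month']} out of 1..12"
            )
        if bool(row["grazing_flag"]):
            inten = float(row["intensity"])
            if not 0.0 <= inten <= 1.0:
                raise ParseError(
                    f"{path}: row {i + 2}: intensity {inten} out of [0, 1]"
                )
            events[(int(row["year"]), int(row["month"]))] = inten
    return GrazingSchedule(events)


def write_schedule(schedule: GrazingSchedule, path: str | Path) -> None:
    rows = [
        {"year": y, "month": m, "grazing_flag": True, "intensity": inten}
        for (y, m), inten in sorted(schedule.events.items())
    ]
    pd.DataFrame(rows, columns=["year", "month", "grazing_flag",
                                "intensity"]).to_csv(path, index=False)


def write_result(result: SimulationResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)
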