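"""Table dialects and run configuration.

All tables are plain CSV with fixed, documented column sets; reads
validate the required columns and raise :class:`SchemaError` listing
anything missing.  Numeric round-trips (write then read) are lossless
at full float precision.  The run configuration is a JSON document
validated by a pydantic model; ``config_json_schema()`` publishes the
schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import simulate as sim
from .errors import SchemaError
from .flow import FLOW_COLUMNS, FlowSample
from .gating import DEFAULT_GATE_PERCENTILE
from .kinetics import RATES_TABLE_COLUMNS, IntensityTimepoint
from .simulate import SNAPSHOT_COLUMNS

MEDIANS_COLUMNS = ("day", "median_au")
PERCENTS_COLUMNS = ("day", "percent_positive")
POINTS_COLUMNS = ("point_id", "x_um", "y_um", "marker")
BOUNDARY_COLUMNS = ("x_um", "y_um")

# Full round-trip precision: repr-style shortest float representation.
_CSV_KW = dict(index=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], kind: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing columns: {missing}", missing)


def read_csv(path) -> pd.DataFrame:
    # C engine parses scientific notation ("1e5") locale-independently;
    # round_trip parsing makes write->read lossless at full precision
    return pd.read_csv(path, float_precision="round_trip")


# -- flow events ------------------------------------------------------------


def write_flow_csv(sample: FlowSample, path) -> Path:
    path = Path(path)
    sample.events.to_csv(path, **_CSV_KW)
    return path


def read_flow_csv(path) -> FlowSample:
    df = read_csv(path)
    _require_columns(df, FLOW_COLUMNS, "flow event")
    day = float(df["day"].iloc[0]) if len(df) else 0.0
    seed = int(df["seed"].iloc[0]) if len(df) else 0
    return FlowSample(events=df, day=day, meta={"seed": seed})


# -- population snapshots ---------------------------------------------------


def write_snapshot_csv(snapshot: sim.PopulationSnapshot, path) -> Path:
    path = Path(path)
    snapshot.to_frame().to_csv(path, **_CSV_KW)
    return path


def read_snapshot_csv(path) -> sim.PopulationSnapshot:
    df = read_csv(path)
    _require_columns(df, SNAPSHOT_COLUMNS, "population snapshot")
    day = float(df["day"].iloc[0]) if len(df) else 0.0
    return sim.PopulationSnapshot(
        day=day,
        intensity_au=df["intensity_au"].to_numpy(float),
        divisions=df["divisions"].to_numpy(np.int64),
        brdu_labeled=df["brdu_labeled"].to_numpy(bool),
        subpop_id=df["subpop_id"].to_numpy(np.int64),
        labeled_at_pulse=df["labeled_at_pulse"].to_numpy(bool),
    )


# -- summary series ---------------------------------------------------------


def write_medians_csv(df: pd.DataFrame, path) -> Path:
    _require_columns(df, MEDIANS_COLUMNS, "median series")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(MEDIANS_COLUMNS)].to_csv(path, **_CSV_KW)
    return Path(path)


def read_medians_csv(path) -> list[IntensityTimepoint]:
    df = read_csv(path)
    _require_columns(df, MEDIANS_COLUMNS, "median series")
    return [
        IntensityTimepoint(float(r.day), float(r.median_au))
        for r in df.itertuples()
    ]


def write_percents_csv(df: pd.DataFrame, path) -> Path:
    _require_columns(df, PERCENTS_COLUMNS, "percent-positive series")
    df.loc[:, list(PERCENTS_COLUMNS)].to_csv(path, **_CSV_KW)
    return Path(path)


def read_percents_csv(path) -> list[tuple[float, float]]:
    df = read_csv(path)
    _require_columns(df, PERCENTS_COLUMNS, "percent-positive series")
    return [(float(r.day), float(r.percent_positive)) for r in df.itertuples()]


def write_rates_csv(df: pd.DataFrame, path) -> Path:
    _require_columns(df, RATES_TABLE_COLUMNS, "rate")
    df.loc[:, list(RATES_TABLE_COLUMNS)].to_csv(path, **_CSV_KW)
    return Path(path)


def read_rates_csv(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, RATES_TABLE_COLUMNS, "rate")
    return df


# -- spatial tables ---------------------------------------------------------


def read_points_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (points (n,2) um, marker flags)."""
    df = read_csv(path)
    _require_columns(df, POINTS_COLUMNS, "section points")
    pts = df[["x_um", "y_um"]].to_numpy(float)
    flags = df["marker"].to_numpy(int).astype(bool)
    return pts, flags


def write_points_csv(points: np.ndarray, marker_flags, path) -> Path:
    points = np.asarray(points, float)
    flags = (
        np.asarray(marker_flags, bool)
        if marker_flags is not None
        else np.zeros(len(points), bool)
    )
    df = pd.DataFrame(
        {
            "point_id": np.arange(len(points), dtype=np.int64),
            "x_um": points[:, 0] if len(points) else np.array([]),
            "y_um": points[:, 1] if len(points) else np.array([]),
            "marker": flags.astype(int),
        }
    )
    df.to_csv(path, **_CSV_KW)
    return Path(path)


def read_boundary_csv(path) -> np.ndarray:
    df = read_csv(path)
    _require_columns(df, BOUNDARY_COLUMNS, "boundary polygon")
    return df[["x_um", "y_um"]].to_numpy(float)


# -- run configuration ------------------------------------------------------


class SimConfigModel(BaseModel):
    n_cells: int = 10_000
    initial_intensity_median: float = 1.0e5
    initial_intensity_cv: float = 0.5
    labeled_fraction_at_start: float = Field(0.936, ge=0, le=1)
    partition_cv: float = Field(0.0, ge=0)
    death_prob_per_day: float = Field(0.0, ge=0, le=1)
    measurement_cv: float = Field(0.2, ge=0)
    autofluorescence_median: float = Field(100.0, ge=0)
    autofluorescence_cv: float = Field(0.5, ge=0)
    contaminant_fraction: float = Field(0.05, ge=0, le=1)
    bead_intensity: float = Field(1.0e4, gt=0)
    bead_cv: float = Field(0.02, ge=0)
    n_bead_events: int = Field(200, gt=0)
    mode: Literal["agent", "mean-field"] = "agent"


class ScheduleModel(BaseModel):
    breakpoints: list[float] = list(sim.PAPER_SCHEDULE.breakpoints)
    rates: list[float] = list(sim.PAPER_SCHEDULE.rates)
    # how the rate values are to be read: decay constants k (per day)
    # or agent-mode daily division probabilities p
    units: Literal["k_per_day", "p_per_day"] = "k_per_day"


class SubpopModel(BaseModel):
    fraction: float = Field(ge=0, le=1)
    rate_multiplier: float = Field(ge=0)


class ProtocolModel(BaseModel):
    sample_days: list[float] = list(sim.PAPER_SAMPLE_DAYS)
    brdu_windows: list[tuple[float, float]] = []
    leak_fraction: float = Field(0.0, ge=0, le=0.05)


class RunConfig(BaseModel):
    """Composite configuration for one end-to-end pipeline run."""

    sim: SimConfigModel = SimConfigModel()
    schedule: ScheduleModel = ScheduleModel()
    subpops: list[SubpopModel] = [
        SubpopModel(fraction=0.75, rate_multiplier=1.0),
        SubpopModel(fraction=0.25, rate_multiplier=0.1),
    ]
    protocol: ProtocolModel = ProtocolModel()
    gate_percentile: float = Field(DEFAULT_GATE_PERCENTILE, gt=0, lt=100)
    bead_target_median_au: float = Field(1.0e4, gt=0)
    medians_source: Literal["positive", "all"] = "positive"
    seed: int = 1

    # -- conversion to domain dataclasses ------------------------------
    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(seed=self.seed, **self.sim.model_dump())

    def rate_schedule(self) -> sim.RateSchedule:
        rates = self.schedule.rates
        if self.schedule.units == "k_per_day" and self.sim.mode == "agent":
            rates = [sim.agent_probability_from_k(k) for k in rates]
        elif self.schedule.units == "p_per_day" and self.sim.mode == "mean-field":
            rates = [sim.k_from_agent_probability(p) for p in rates]
        return sim.RateSchedule(tuple(self.schedule.breakpoints), tuple(rates))

    def subpop_specs(self) -> tuple[sim.SubpopulationSpec, ...]:
        return tuple(
            sim.SubpopulationSpec(s.fraction, s.rate_multiplier) for s in self.subpops
        )

    def pulse_protocol(self) -> sim.PulseChaseProtocol:
        return sim.PulseChaseProtocol(
            sample_days=tuple(self.protocol.sample_days),
            brdu_windows=tuple(self.protocol.brdu_windows),
            leak_fraction=self.protocol.leak_fraction,
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        raise SchemaError(f"invalid run configuration: {err}") from err


def save_run_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n")
    return path


def config_json_schema() -> dict:
    """Published JSON schema for the run-configuration document."""
    return RunConfig.model_json_schema()
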