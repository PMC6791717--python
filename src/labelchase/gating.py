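"""Gating and summary statistics for flow event tables.

Implements the analysis conventions of the experiment: intensities are
first normalized so that the calibration-bead median matches a fixed
standard (making acquisitions comparable across days and instrument
settings), the positive/negative gate is placed at a high percentile of
the negative-control population, and the summaries of record are the
percent of label-positive events and the median intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptySelectionError, MissingControlError
from .flow import ROLE_NEGATIVE, FlowSample

DEFAULT_GATE_PERCENTILE = 99.5
MIN_BEAD_EVENTS = 10


@dataclass(frozen=True)
class Gate:
    """A positive/negative intensity threshold, with its provenance."""

    threshold_au: float
    source: str = ""

    def __post_init__(self):
        if self.threshold_au <= 0:
            raise ConfigError("gate threshold must be > 0")


@dataclass(frozen=True)
class BeadStandard:
    """Target median intensity for calibration-bead events."""

    target_median_au: float

    def __post_init__(self):
        if self.target_median_au <= 0:
            raise ConfigError("bead target median must be > 0")


def normalize_to_beads(sample: FlowSample, standard: BeadStandard) -> FlowSample:
    """Rescale all intensities so the bead median equals the standard.

    Every event (cells and beads alike) is multiplied by
    ``target_median_au / median(bead intensities)``, so the bead median
    afterwards equals the target exactly and the operation is
    idempotent.  Contaminant-flagged events are dropped here, mirroring
    FACS exclusion of CD31+/CD45+ cells before analysis.
    """
    beads = sample.bead_intensities()
    if len(beads) == 0:
        raise MissingControlError(
            "no calibration-bead events in sample; bead normalization "
            "requires the bead control"
        )
    if len(beads) < MIN_BEAD_EVENTS:
        raise MissingControlError(
            f"only {len(beads)} bead events (need >= {MIN_BEAD_EVENTS})"
        )
    scale = standard.target_median_au / float(np.median(beads))
    events = sample.events.loc[~sample.events["is_contaminant"]].copy()
    events["intensity_au"] = events["intensity_au"].to_numpy(float) * scale
    events.reset_index(drop=True, inplace=True)
    meta = dict(sample.meta)
    meta["bead_scale"] = meta.get("bead_scale", 1.0) * scale
    return FlowSample(events=events, day=sample.day, meta=meta)


def gate_from_negative_control(
    negative: FlowSample, percentile: float = DEFAULT_GATE_PERCENTILE
) -> Gate:
    """Place the gate at a percentile of the negative-control intensities.

    Uses linear interpolation between order statistics, so at the
    default 99.5th percentile at most 0.5 % of negative-control events
    exceed the threshold — consistent with the sub-1 % background
    measured in uninduced (no-Dox) controls.
    """
    if not (0.0 < percentile < 100.0):
        raise ConfigError("percentile must lie in (0, 100)")
    neg = negative.negative_intensities()
    if len(neg) == 0:
        raise MissingControlError("no negative-control events; cannot place gate")
    threshold = float(np.percentile(neg, percentile, method="linear"))
    return Gate(
        threshold_au=threshold,
        source=f"p{percentile:g} of {len(neg)} negative-control events",
    )


def percent_positive(sample: FlowSample, gate: Gate) -> float:
    """Percent of analysis events strictly above the gate, in [0, 100]."""
    intens = sample.analysis_intensities()
    if len(intens) == 0:
        raise EmptySelectionError("no analysis events after excluding beads/contaminants")
    return 100.0 * float(np.mean(intens > gate.threshold_au))


def median_intensity(
    sample: FlowSample, gate: Gate | None = None, positives_only: bool = False
) -> float:
    """Median analysis intensity, optionally of gate-positive events only.

    Even-count medians are the mean of the central pair.  An empty
    selection (e.g. no positive events) raises
    :class:`~labelchase.errors.EmptySelectionError`, which is
    deliberately distinguishable from a legitimate zero.
    """
    intens = sample.analysis_intensities()
    if positives_only:
        if gate is None:
            raise ConfigError("positives_only requires a gate")
        intens = intens[intens > gate.threshold_au]
    if len(intens) == 0:
        raise EmptySelectionError("no events in the requested selection")
    return float(np.median(intens))


def summarize_sample(
    sample: FlowSample,
    standard: BeadStandard,
    percentile: float = DEFAULT_GATE_PERCENTILE,
) -> dict:
    """Normalize, gate and summarize one acquisition.

    Returns the summary row of record: day, percent positive, median of
    all events, median of positives (NaN when there are none), the gate
    threshold and the number of analysis events.
    """
    norm = normalize_to_beads(sample, standard)
    gate = gate_from_negative_control(norm, percentile)
    pct = percent_positive(norm, gate)
    med_all = median_intensity(norm)
    try:
        med_pos = median_intensity(norm, gate, positives_only=True)
    except EmptySelectionError:
        med_pos = float("nan")
    return {
        "day": float(sample.day),
        "percent_positive": pct,
        "median_all_au": med_all,
        "median_positive_au": med_pos,
        "gate_au": gate.threshold_au,
        "n_events": int(len(norm.analysis_intensities())),
    }


def summarize_series(
    samples: list[FlowSample],
    standard: BeadStandard,
    percentile: float = DEFAULT_GATE_PERCENTILE,
) -> pd.DataFrame:
    """Summary table over a chase time series, one row per sample day."""
    rows = [summarize_sample(s, standard, percentile) for s in samples]
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
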