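"""Flow-cytometry event tables.

A :class:`FlowSample` is the in-memory form of one acquisition: one row
per detected event with its fluorescence intensity (arbitrary units) and
bookkeeping flags.  A single sample may carry several *roles* — the
tendon-cell events themselves, a paired negative-control population run
through the same instrument settings, calibration-bead events, and
contaminant events (CD31+/CD45+-like cells that FACS exclusion removes
before analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

ROLE_TENDON = "tendon"
ROLE_NEGATIVE = "negative_control"

#: Columns of the flow-event CSV dialect.
FLOW_COLUMNS = (
    "event_id",
    "intensity_au",
    "is_contaminant",
    "is_bead",
    "sample_role",
    "day",
    "seed",
)


@dataclass
class FlowSample:
    """A set of measured fluorescence events at one chase day.

    Parameters
    ----------
    events
        DataFrame with at least the columns in :data:`FLOW_COLUMNS`.
    day
        Chase day of the acquisition (day 0 = start of chase).
    meta
        Free-form provenance (seed, config reference).
    """

    events: pd.DataFrame
    day: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FLOW_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(
                f"flow event table is missing columns: {missing}", missing
            )
        inten = self.events["intensity_au"].to_numpy(float)
        if np.any(inten < 0):
            raise SchemaError("event intensities must be >= 0")
        roles = set(self.events["sample_role"].unique())
        bad = roles - {ROLE_TENDON, ROLE_NEGATIVE}
        if bad:
            raise SchemaError(f"unknown sample roles: {sorted(bad)}")

    # -- selections ----------------------------------------------------
    def _mask(self, role: str, beads: bool | None, contaminants: bool | None):
        m = self.events["sample_role"] == role
        if beads is not None:
            m &= self.events["is_bead"] == beads
        if contaminants is not None:
            m &= self.events["is_contaminant"] == contaminants
        return m

    def analysis_intensities(self) -> np.ndarray:
        """Tendon-event intensities with beads and contaminants excluded."""
        m = self._mask(ROLE_TENDON, beads=False, contaminants=False)
        return self.events.loc[m, "intensity_au"].to_numpy(float)

    def negative_intensities(self) -> np.ndarray:
        m = self._mask(ROLE_NEGATIVE, beads=False, contaminants=False)
        return self.events.loc[m, "intensity_au"].to_numpy(float)

    def bead_intensities(self) -> np.ndarray:
        m = self.events["is_bead"] == True  # noqa: E712  (pandas elementwise)
        return self.events.loc[m, "intensity_au"].to_numpy(float)

    @property
    def n_events(self) -> int:
        return int(len(self.events))

    def copy(self) -> "FlowSample":
        return FlowSample(self.events.copy(), self.day, dict(self.meta))


def concat_events(*frames: pd.DataFrame) -> pd.DataFrame:
    out = pd.concat(frames, ignore_index=True)
    out["event_id"] = np.arange(len(out), dtype=np.int64)
    return out


def make_event_frame(
    intensities: np.ndarray,
    *,
    role: str,
    day: float,
    seed: int,
    is_contaminant: bool = False,
    is_bead: bool = False,
) -> pd.DataFrame:
    n = len(intensities)
    return pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=np.int64),
            "intensity_au": np.asarray(intensities, float),
            "is_contaminant": np.full(n, is_contaminant),
            "is_bead": np.full(n, is_bead),
            "sample_role": np.full(n, role, dtype=object),
            "day": np.full(n, float(day)),
            "seed": np.full(n, int(seed), dtype=np.int64),
        }
    )
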