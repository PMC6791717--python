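"""Stochastic forward model of a pulse-chase label-dilution experiment.

The generator emulates a population of tendon cells that carries a
heritable nuclear label (an H2B-GFP-like fusion) induced during a
doxycycline pulse ending at birth.  During the chase the label is not
replenished; every cell division splits the parent's label between the
two daughters, so per-cell intensity halves (on average) per division
and the division history of a cell is encoded in its fluorescence.
Thymidine-analog labeling (BrdU/EdU) is modeled as a window of days
during which any division marks both daughters.

Two operating modes are provided:

``"agent"``
    A discrete-day branching process.  Each cell independently divides
    with its daily probability *p*; a dividing cell of intensity *I* is
    replaced by daughters ``f*I`` and ``(1-f)*I`` with *f* symmetric
    around 0.5 (exactly 0.5 when ``partition_cv == 0``).  Total label is
    conserved exactly, and with exact halving every cell obeys
    ``intensity = I0 * 2**(-divisions)``.

``"mean-field"``
    Deterministic dilution of the labeled pool: every labeled cell's
    intensity is multiplied by ``exp(-k)`` per day, with no stochastic
    division.  Because the downstream decay-rate estimator is defined on
    median intensity, mean-field runs make the inference exactly
    invertible and are the preferred source of recovery fixtures.

Rates are calibrated against the published daily proliferation rates
(19, 9, 3.85, 1.75 and 0.1 % per day over postnatal days 0-7, 7-14,
14-21, 21-80 and 80-600).  In mean-field mode the schedule's values are
the decay constants ``k`` (per day) directly.  In agent mode the daily
division probability *p* that reproduces a median-intensity decay ``k``
is obtained from the lineage (spine) law: a uniformly sampled cell's
lineage divides with probability ``2p/(1+p)`` per day, so
``k = ln2 * 2p/(1+p)`` and hence ``p = k / (2 ln2 - k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ScheduleCoverageError
from .flow import (
    ROLE_NEGATIVE,
    ROLE_TENDON,
    FlowSample,
    concat_events,
    make_event_frame,
)

LN2 = math.log(2.0)

MODE_AGENT = "agent"
MODE_MEAN_FIELD = "mean-field"

#: Columns of the population-snapshot CSV dialect.
SNAPSHOT_COLUMNS = (
    "cell_id",
    "day",
    "intensity_au",
    "divisions",
    "brdu_labeled",
    "subpop_id",
    "labeled_at_pulse",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellAgent:
    """One simulated cell (scalar view; populations are stored as arrays)."""

    intensity_au: float
    divisions: int
    brdu_labeled: bool
    subpop_id: int
    labeled_at_pulse: bool

    def __post_init__(self):
        if self.intensity_au < 0:
            raise ConfigError("cell intensity must be >= 0")
        if self.divisions < 0:
            raise ConfigError("division count must be >= 0")


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant per-day rates over chase days.

    ``breakpoints`` has one more entry than ``rates``; ``rates[i]``
    applies on the half-open interval ``[breakpoints[i],
    breakpoints[i+1])``.  The interpretation of the values depends on
    the simulation mode: daily division probabilities *p* in agent
    mode, decay constants *k* (per day) in mean-field mode; see
    :func:`agent_probability_from_k` to convert.
    """

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        r = tuple(float(x) for x in self.rates)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", r)
        if len(bp) != len(r) + 1:
            raise ConfigError(
                "need exactly one rate per interval "
                f"({len(bp)} breakpoints, {len(r)} rates)"
            )
        if any(b1 >= b2 for b1, b2 in zip(bp, bp[1:])):
            raise ConfigError("breakpoints must be strictly increasing")
        if any(not (0.0 <= x <= 1.0) for x in r):
            raise ConfigError("rates must lie in [0, 1]")

    def covers(self, day: float) -> bool:
        return self.breakpoints[0] <= day < self.breakpoints[-1]

    def rate_at(self, day: float) -> float:
        if not self.covers(day):
            raise ScheduleCoverageError(
                f"day {day} outside schedule coverage "
                f"[{self.breakpoints[0]}, {self.breakpoints[-1]})"
            )
        idx = int(np.searchsorted(self.breakpoints, day, side="right") - 1)
        return self.rates[idx]

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.breakpoints[:-1], self.breakpoints[1:]))


def agent_probability_from_k(k_per_day: float) -> float:
    """Daily division probability reproducing median-intensity decay ``k``.

    Inverts the spine law ``k = ln2 * 2p/(1+p)``.
    """
    if not (0.0 <= k_per_day < 2.0 * LN2):
        raise ConfigError(f"k={k_per_day} has no valid division probability")
    return k_per_day / (2.0 * LN2 - k_per_day)


def k_from_agent_probability(p: float) -> float:
    """Median-intensity decay constant implied by division probability p."""
    if not (0.0 <= p <= 1.0):
        raise ConfigError("p must lie in [0, 1]")
    return LN2 * 2.0 * p / (1.0 + p)


#: Published interval decay constants (per day) on chase days 0-600:
#: 19, 9, 3.85, 1.75 and 0.1 percent per day.  Used verbatim in
#: mean-field mode; converted via :func:`agent_probability_from_k`
#: for agent-mode runs.
PAPER_SCHEDULE = RateSchedule(
    breakpoints=(0.0, 7.0, 14.0, 21.0, 80.0, 600.0),
    rates=(0.19, 0.09, 0.0385, 0.0175, 0.001),
)

#: The same schedule expressed as agent-mode daily division probabilities.
PAPER_AGENT_SCHEDULE = RateSchedule(
    breakpoints=PAPER_SCHEDULE.breakpoints,
    rates=tuple(agent_probability_from_k(k) for k in PAPER_SCHEDULE.rates),
)

#: Chase days at which the experiment sampled the population.
PAPER_SAMPLE_DAYS = (0.0, 7.0, 14.0, 21.0, 80.0, 600.0)


@dataclass(frozen=True)
class SubpopulationSpec:
    """A kinetic subpopulation: a share of cells dividing at a scaled rate.

    ``rate_multiplier`` scales the schedule's daily rate (the resulting
    probability is capped at 1).  The default population mixes a fast
    majority with a slow label-retaining minority so that a positive
    plateau persists after long chases; the split is a modeling choice,
    not an inferred per-cell rate distribution.
    """

    fraction: float
    rate_multiplier: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigError("subpopulation fraction must lie in [0, 1]")
        if self.rate_multiplier < 0:
            raise ConfigError("rate multiplier must be >= 0")


DEFAULT_SUBPOPS = (
    SubpopulationSpec(fraction=0.75, rate_multiplier=1.0),
    SubpopulationSpec(fraction=0.25, rate_multiplier=0.1),
)


def _check_subpops(subpops: Sequence[SubpopulationSpec]):
    total = sum(s.fraction for s in subpops)
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"subpopulation fractions sum to {total}, not 1")


@dataclass(frozen=True)
class PulseChaseProtocol:
    """Sampling days, thymidine-analog windows and pulse leakiness.

    ``brdu_windows`` are half-open day intervals ``[start, end)``; a
    division during day ``d`` confers BrdU on both daughters iff
    ``start <= d < end`` for some window.  ``leak_fraction`` is the
    probability that a cell is labeled despite no induction pulse
    (no-Dox control runs; the measured background is below 1 %).
    """

    sample_days: tuple[float, ...] = PAPER_SAMPLE_DAYS
    brdu_windows: tuple[tuple[float, float], ...] = ()
    leak_fraction: float = 0.0

    def __post_init__(self):
        days = tuple(float(d) for d in self.sample_days)
        object.__setattr__(self, "sample_days", days)
        wins = tuple((float(a), float(b)) for a, b in self.brdu_windows)
        object.__setattr__(self, "brdu_windows", wins)
        if any(d < 0 for d in days):
            raise ConfigError("sample days must be nonnegative")
        if any(d1 > d2 for d1, d2 in zip(days, days[1:])):
            raise ConfigError("sample days must be sorted")
        for a, b in wins:
            if a > b:
                raise ConfigError(f"BrdU window start {a} after end {b}")
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            if a2 < b1:
                raise ConfigError("BrdU windows must not overlap")
        if not (0.0 <= self.leak_fraction <= 0.05):
            raise ConfigError("leak_fraction must lie in [0, 0.05]")

    def in_brdu_window(self, day: float) -> bool:
        return any(a <= day < b for a, b in self.brdu_windows)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated pulse-chase run.

    Defaults reproduce the experiment's reported scales: a chase that
    starts with 93.6 % of cells labeled at a median of 1e5 AU, cellular
    autofluorescence near 1e2 AU (two decades below the 1e3 AU
    detection threshold), and exact label halving per division.
    """

    n_cells: int = 10_000
    initial_intensity_median: float = 1.0e5
    initial_intensity_cv: float = 0.5
    labeled_fraction_at_start: float = 0.936
    partition_cv: float = 0.0
    death_prob_per_day: float = 0.0
    measurement_cv: float = 0.2
    autofluorescence_median: float = 1.0e2
    autofluorescence_cv: float = 0.5
    contaminant_fraction: float = 0.05
    bead_intensity: float = 1.0e4
    bead_cv: float = 0.02
    n_bead_events: int = 200
    seed: int = 0
    mode: str = MODE_AGENT

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be > 0")
        if self.initial_intensity_median <= 0:
            raise ConfigError("initial intensity median must be > 0")
        for name in (
            "labeled_fraction_at_start",
            "death_prob_per_day",
            "contaminant_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        for name in (
            "initial_intensity_cv",
            "partition_cv",
            "measurement_cv",
            "autofluorescence_cv",
            "bead_cv",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.autofluorescence_median < 0 or self.bead_intensity <= 0:
            raise ConfigError("intensity scales must be positive")
        if self.mode not in (MODE_AGENT, MODE_MEAN_FIELD):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def noise_free(self) -> "SimConfig":
        """A copy with all measurement noise switched off."""
        return replace(
            self,
            initial_intensity_cv=0.0,
            partition_cv=0.0,
            measurement_cv=0.0,
            autofluorescence_median=0.0,
            contaminant_fraction=0.0,
            bead_cv=0.0,
        )


@dataclass
class PopulationSnapshot:
    """The full cell population at one chase day (array-of-structs)."""

    day: float
    intensity_au: np.ndarray
    divisions: np.ndarray
    brdu_labeled: np.ndarray
    subpop_id: np.ndarray
    labeled_at_pulse: np.ndarray

    def __post_init__(self):
        n = len(self.intensity_au)
        for name in ("divisions", "brdu_labeled", "subpop_id", "labeled_at_pulse"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"field {name} length mismatch")

    @property
    def population_size(self) -> int:
        return int(len(self.intensity_au))

    @property
    def total_intensity(self) -> float:
        return float(self.intensity_au.sum())

    def cells(self) -> Iterator[CellAgent]:
        for i in range(self.population_size):
            yield CellAgent(
                float(self.intensity_au[i]),
                int(self.divisions[i]),
                bool(self.brdu_labeled[i]),
                int(self.subpop_id[i]),
                bool(self.labeled_at_pulse[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.population_size, dtype=np.int64),
                "day": np.full(self.population_size, self.day),
                "intensity_au": self.intensity_au,
                "divisions": self.divisions,
                "brdu_labeled": self.brdu_labeled,
                "subpop_id": self.subpop_id,
                "labeled_at_pulse": self.labeled_at_pulse,
            }
        )

    def copy(self) -> "PopulationSnapshot":
        return PopulationSnapshot(
            self.day,
            self.intensity_au.copy(),
            self.divisions.copy(),
            self.brdu_labeled.copy(),
            self.subpop_id.copy(),
            self.labeled_at_pulse.copy(),
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, median: float, cv: float, n: int):
    """Log-scale draws with the given *median* and coefficient of variation."""
    if median == 0.0:
        return np.zeros(n)
    if cv == 0.0:
        return np.full(n, float(median))
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=n)


def _effective_probs(
    base: float, subpops: Sequence[SubpopulationSpec]
) -> np.ndarray:
    return np.array(
        [min(1.0, base * s.rate_multiplier) for s in subpops], dtype=float
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_population(
    config: SimConfig,
    subpops: Sequence[SubpopulationSpec] = DEFAULT_SUBPOPS,
    protocol: PulseChaseProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationSnapshot:
    """Construct the day-0 population at the end of the labeling pulse.

    Each cell is labeled with probability ``labeled_fraction_at_start``
    plus, among the remainder, the protocol's ``leak_fraction`` (leaky
    expression without induction).  Labeled cells draw intensity from a
    log-scale distribution with median ``initial_intensity_median``;
    unlabeled cells draw from the autofluorescence distribution.  All
    cells start with zero recorded divisions.
    """
    _check_subpops(subpops)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    leak = protocol.leak_fraction if protocol is not None else 0.0
    p_label = config.labeled_fraction_at_start
    p_eff = p_label + (1.0 - p_label) * leak

    labeled = rng.random(n) < p_eff
    intensity = np.empty(n, dtype=float)
    n_lab = int(labeled.sum())
    intensity[labeled] = _lognormal(
        rng, config.initial_intensity_median, config.initial_intensity_cv, n_lab
    )
    intensity[~labeled] = _lognormal(
        rng, config.autofluorescence_median, config.autofluorescence_cv, n - n_lab
    )

    fracs = np.array([s.fraction for s in subpops])
    subpop_id = rng.choice(len(subpops), size=n, p=fracs / fracs.sum())

    return PopulationSnapshot(
        day=0.0,
        intensity_au=intensity,
        divisions=np.zeros(n, dtype=np.int64),
        brdu_labeled=np.zeros(n, dtype=bool),
        subpop_id=subpop_id.astype(np.int64),
        labeled_at_pulse=labeled,
    )


def advance_day(
    snapshot: PopulationSnapshot,
    schedule: RateSchedule,
    config: SimConfig,
    subpops: Sequence[SubpopulationSpec] = DEFAULT_SUBPOPS,
    protocol: PulseChaseProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationSnapshot:
    """Advance the population by one day (snapshot.day -> day + 1).

    Agent mode: Bernoulli division per cell at its subpopulation's
    daily probability, label partitioned ``f : 1-f`` between daughters,
    then removal with ``death_prob_per_day``.  Mean-field mode: labeled
    intensities are multiplied by ``exp(-k)``; no divisions occur.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if protocol is None:
        protocol = PulseChaseProtocol(sample_days=())
    day = snapshot.day
    rate = schedule.rate_at(day)  # raises if uncovered

    if config.mode == MODE_MEAN_FIELD:
        out = snapshot.copy()
        lab = out.labeled_at_pulse
        out.intensity_au[lab] *= math.exp(-rate)
        out.day = day + 1.0
        return out

    _check_subpops(subpops)
    p_by_subpop = _effective_probs(rate, subpops)
    p_cell = p_by_subpop[snapshot.subpop_id]
    divides = rng.random(snapshot.population_size) < p_cell

    keep_i = snapshot.intensity_au[~divides]
    keep_d = snapshot.divisions[~divides]
    keep_b = snapshot.brdu_labeled[~divides]
    keep_s = snapshot.subpop_id[~divides]
    keep_l = snapshot.labeled_at_pulse[~divides]

    n_div = int(divides.sum())
    parent_i = snapshot.intensity_au[divides]
    if config.partition_cv == 0.0:
        f = np.full(n_div, 0.5)
    else:
        # partition fraction symmetric around 1/2; cv is relative to 1/2
        f = np.clip(rng.normal(0.5, 0.5 * config.partition_cv, n_div), 0.0, 1.0)
    d1 = parent_i * f
    d2 = parent_i * (1.0 - f)
    child_d = snapshot.divisions[divides] + 1
    child_b = snapshot.brdu_labeled[divides] | protocol.in_brdu_window(day)
    child_s = snapshot.subpop_id[divides]
    child_l = snapshot.labeled_at_pulse[divides]

    intensity = np.concatenate([keep_i, d1, d2])
    divisions = np.concatenate([keep_d, child_d, child_d])
    brdu = np.concatenate([keep_b, child_b, child_b])
    subpop = np.concatenate([keep_s, child_s, child_s])
    labeled = np.concatenate([keep_l, child_l, child_l])

    if config.death_prob_per_day > 0.0:
        alive = rng.random(len(intensity)) >= config.death_prob_per_day
        intensity = intensity[alive]
        divisions = divisions[alive]
        brdu = brdu[alive]
        subpop = subpop[alive]
        labeled = labeled[alive]

    return PopulationSnapshot(
        day=day + 1.0,
        intensity_au=intensity,
        divisions=divisions,
        brdu_labeled=brdu,
        subpop_id=subpop,
        labeled_at_pulse=labeled,
    )


def run_pulse_chase(
    config: SimConfig,
    schedule: RateSchedule,
    subpops: Sequence[SubpopulationSpec] = DEFAULT_SUBPOPS,
    protocol: PulseChaseProtocol = PulseChaseProtocol(),
) -> list[PopulationSnapshot]:
    """Run the chase and return snapshots at the protocol's sample days.

    Deterministic given ``config.seed``; the day-0 snapshot is exactly
    the :func:`build_population` output.
    """
    if not protocol.sample_days:
        raise ConfigError("protocol has no sample days")
    if any(d != int(d) for d in protocol.sample_days):
        raise ConfigError("sample days must be whole days (daily time step)")
    last = max(protocol.sample_days)
    if last > 0 and not schedule.covers(last - 1):
        raise ScheduleCoverageError(
            f"sample day {last} requires schedule coverage up to day {last}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pop = build_population(config, subpops, protocol, rng)
    wanted = set(protocol.sample_days)
    out: list[PopulationSnapshot] = []
    if 0.0 in wanted:
        out.append(pop.copy())
    day = 0.0
    while day < last:
        pop = advance_day(pop, schedule, config, subpops, protocol, rng)
        day = pop.day
        if day in wanted:
            out.append(pop.copy())
    return out


def measure_flow(
    snapshot: PopulationSnapshot,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> FlowSample:
    """Pass a population through the flow-cytometry measurement model.

    Each cell yields one event: true intensity times multiplicative
    log-scale noise (CV ``measurement_cv``) plus an additive
    autofluorescence draw.  Contaminant events (a ``contaminant_fraction``
    share of the final tendon events), calibration-bead events at
    ``bead_intensity`` and a paired negative-control population (unlabeled
    cells through the same model) are appended and flagged.
    """
    if snapshot.population_size == 0:
        raise ConfigError("cannot measure an empty population")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = snapshot.population_size

    def measured(true_intensity: np.ndarray) -> np.ndarray:
        m = len(true_intensity)
        noise = _lognormal(rng, 1.0, config.measurement_cv, m)
        background = _lognormal(
            rng, config.autofluorescence_median, config.autofluorescence_cv, m
        )
        return true_intensity * noise + background

    tendon = make_event_frame(
        measured(snapshot.intensity_au),
        role=ROLE_TENDON,
        day=snapshot.day,
        seed=config.seed,
    )

    frames = [tendon]
    cf = config.contaminant_fraction
    if cf > 0.0:
        # extra events so that the expected contaminant share of all
        # tendon-role events equals contaminant_fraction
        m = int(rng.binomial(n, cf / (1.0 - cf)))
        if m > 0:
            contam_true = _lognormal(
                rng, config.autofluorescence_median, config.autofluorescence_cv, m
            )
            frames.append(
                make_event_frame(
                    measured(contam_true),
                    role=ROLE_TENDON,
                    day=snapshot.day,
                    seed=config.seed,
                    is_contaminant=True,
                )
            )

    beads = _lognormal(rng, config.bead_intensity, config.bead_cv, config.n_bead_events)
    frames.append(
        make_event_frame(
            beads,
            role=ROLE_TENDON,
            day=snapshot.day,
            seed=config.seed,
            is_bead=True,
        )
    )

    neg_true = _lognormal(
        rng, config.autofluorescence_median, config.autofluorescence_cv, n
    )
    frames.append(
        make_event_frame(
            measured(neg_true),
            role=ROLE_NEGATIVE,
            day=snapshot.day,
            seed=config.seed,
        )
    )

    return FlowSample(
        events=concat_events(*frames),
        day=snapshot.day,
        meta={"seed": config.seed, "mode": config.mode},
    )
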