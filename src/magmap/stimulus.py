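"""Experimental stimulus sequences for magnitude-mapping runs.

Four run types probe duration and numerosity tuning with slowly moving
dot arrays: two baselines that vary a single magnitude (T: duration,
N: numerosity), and two interaction conditions that vary both together,
either congruently (C: more dots shown for longer) or incongruently
(I: more dots shown for shorter).  Every run is 13 cycles of 10 trials;
within a cycle the varying magnitude sweeps its five levels ascending
then descending, a red-dot target appears on exactly one trial per
cycle, and each cycle onset is locked to the scanner TR grid.

Physical magnitudes are mapped to a common arbitrary-unit axis
(0 at the smallest tested value, 100 at the largest, log-linear in
between) so duration and numerosity tuning can be compared directly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("T", "N", "C", "I")

#: Numerosity levels (dot counts).  These do not follow the geometric rule
#: the duration levels obey, so they are kept as explicit literals.
NUMEROSITY_LEVELS = (1.0, 2.0, 7.0, 19.0, 50.0)


@dataclass(frozen=True)
class MagnitudeAxis:
    """One magnitude dimension with its tested physical range.

    The arbitrary-unit mapping sends ``physical_min`` to 0 and
    ``physical_max`` to 100, log-linearly in between.
    """

    name: str
    physical_min: float
    physical_max: float
    n_levels: int = 5
    #: Optional explicit level set overriding geometric spacing.
    levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.physical_min <= 0 or self.physical_max <= 0:
            raise ValueError("magnitude axis bounds must be positive")
        if self.physical_max <= self.physical_min:
            raise ValueError("physical_max must exceed physical_min")
        if self.n_levels < 2:
            raise ValueError("an axis needs at least two levels")


#: Durations tested: 0.3 to 0.9 s, five geometric steps.
DURATION_AXIS = MagnitudeAxis("duration", 0.3, 0.9, 5)
#: Numerosities tested: 1 to 50 dots, five hand-picked levels.
NUMEROSITY_AXIS = MagnitudeAxis("numerosity", 1.0, 50.0, 5, levels=NUMEROSITY_LEVELS)


def make_levels(axis: MagnitudeAxis) -> np.ndarray:
    """Return the ordered physical level set of an axis.

    Explicit literal levels win when present; otherwise ``n_levels``
    geometrically spaced values from ``physical_min`` to ``physical_max``
    with exact endpoints.
    """
    if axis.levels is not None:
        return np.asarray(axis.levels, dtype=float)
    levels = np.geomspace(axis.physical_min, axis.physical_max, axis.n_levels)
    levels[0] = axis.physical_min
    levels[-1] = axis.physical_max
    return levels


def to_units(value, axis: MagnitudeAxis):
    """Map physical magnitude(s) to arbitrary units in [0, 100].

    ``unit = 100 * log(value/min) / log(max/min)``.  Values outside the
    tested range are clamped with a warning; non-positive values are an
    error (the log mapping is undefined there).
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("physical magnitudes must be positive")
    lo, hi = axis.physical_min, axis.physical_max
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(
            f"{axis.name} value outside tested range [{lo}, {hi}]; clamping",
            stacklevel=2,
        )
        arr = np.clip(arr, lo, hi)
    units = 100.0 * (np.log(arr) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return units if units.ndim else float(units)


@dataclass(frozen=True)
class TimingConfig:
    """Run timing.  ``iti`` is the trial onset-to-onset interval (SOA);
    ``ici`` is the gap appended after each cycle before snapping the next
    cycle onset up to the TR grid."""

    tr: float = 1.25
    iti: float = 1.5
    ici: float = 5.0
    n_cycles: int = 13
    trials_per_cycle: int = 10
    fixed_numerosity: float = 100.0  # dots shown throughout T runs
    fixed_duration: float = 0.2  # display time throughout N runs
    tail: float = 20.0  # post-run acquisition covering the HRF tail


@dataclass(frozen=True)
class StimulusEvent:
    trial_index: int
    cycle_index: int
    onset: float
    duration: float
    numerosity: float
    is_target: bool


@dataclass(frozen=True)
class StimulusSequence:
    """One run: ordered events plus the acquisition grid they sit on."""

    condition: str
    events: tuple[StimulusEvent, ...]
    tr: float
    n_volumes: int
    iti: float
    ici: float
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per event."""
        return pd.DataFrame(
            {
                "trial": [e.trial_index for e in self.events],
                "cycle": [e.cycle_index for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "numerosity": [e.numerosity for e in self.events],
                "is_target": [e.is_target for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_bids_events(self, path) -> None:
        """BIDS-style events TSV (onset, duration, trial_type)."""
        df = self.to_frame()
        out = pd.DataFrame(
            {
                "onset": df["onset_s"],
                "duration": df["duration_s"],
                "trial_type": [
                    f"{self.condition}_target" if t else self.condition
                    for t in df["is_target"]
                ],
                "numerosity": df["numerosity"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


def _sweep(n_levels: int) -> list[int]:
    """Level indices ascending then descending: 0..4,4..0."""
    up = list(range(n_levels))
    return up + up[::-1]


def _antisweep(n_levels: int) -> list[int]:
    """Level indices descending then ascending: 4..0,0..4 — paired with
    the ascending sweep this anti-correlates the two magnitudes."""
    down = list(range(n_levels - 1, -1, -1))
    return down + down[::-1]


def _target_positions(n_cycles: int, trials_per_cycle: int, rng: np.random.Generator) -> np.ndarray:
    """One target slot per cycle, counterbalanced: a shuffled pass through
    all within-cycle positions, topped up with distinct extra draws."""
    pos: list[int] = []
    while len(pos) < n_cycles:
        k = min(trials_per_cycle, n_cycles - len(pos))
        pos.extend(rng.permutation(trials_per_cycle)[:k].tolist())
    return np.asarray(pos[:n_cycles])


def build_run(
    condition: str,
    timing: TimingConfig | None = None,
    seed: int = 0,
    duration_axis: MagnitudeAxis = DURATION_AXIS,
    numerosity_axis: MagnitudeAxis = NUMEROSITY_AXIS,
) -> StimulusSequence:
    """Generate one run of the given condition.

    Per cycle the varying magnitude(s) traverse their five levels
    ascending then descending.  T fixes numerosity, N fixes duration,
    C pairs the sweeps so both magnitudes rise and fall together, and I
    anti-pairs them (duration falls 0.9 to 0.3 s while numerosity rises
    1 to 50 dots, then the reverse).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    timing = timing or TimingConfig()
    dur_levels = make_levels(duration_axis)
    num_levels = make_levels(numerosity_axis)
    if timing.iti <= max(dur_levels.max(), timing.fixed_duration):
        raise ValueError("iti must exceed the longest stimulus duration (overlapping trials)")

    n = len(dur_levels)
    asc = _sweep(n)  # ascending then descending level indices
    desc = _antisweep(n)  # descending then ascending
    if condition == "T":
        durations = [dur_levels[i] for i in asc]
        numerosities = [timing.fixed_numerosity] * len(asc)
    elif condition == "N":
        durations = [timing.fixed_duration] * len(asc)
        numerosities = [num_levels[i] for i in asc]
    elif condition == "C":
        durations = [dur_levels[i] for i in asc]
        numerosities = [num_levels[i] for i in asc]
    else:  # I
        durations = [dur_levels[i] for i in desc]
        numerosities = [num_levels[i] for i in asc]

    rng = np.random.default_rng(seed)
    targets = _target_positions(timing.n_cycles, timing.trials_per_cycle, rng)

    events: list[StimulusEvent] = []
    t = 0.0
    trial = 0
    for cyc in range(timing.n_cycles):
        # snap the cycle onset up to the TR grid, never truncating a trial
        cycle_onset = math.ceil(round(t / timing.tr, 9) - 1e-9) * timing.tr
        cycle_onset = round(cycle_onset, 9)
        for k in range(timing.trials_per_cycle):
            events.append(
                StimulusEvent(
                    trial_index=trial,
                    cycle_index=cyc,
                    onset=round(cycle_onset + k * timing.iti, 9),
                    duration=durations[k],
                    numerosity=numerosities[k],
                    is_target=bool(k == targets[cyc]),
                )
            )
            trial += 1
        t = cycle_onset + timing.trials_per_cycle * timing.iti + timing.ici

    last = events[-1]
    n_volumes = math.ceil((last.onset + last.duration + timing.tail) / timing.tr)
    return StimulusSequence(
        condition=condition,
        events=tuple(events),
        tr=timing.tr,
        n_volumes=n_volumes,
        iti=timing.iti,
        ici=timing.ici,
        seed=seed,
    )


def read_sequence_csv(path, condition: str, tr: float = 1.25, iti: float = 1.5,
                      ici: float = 5.0, seed: int = -1, tail: float = 20.0) -> StimulusSequence:
    """Rebuild a StimulusSequence from its tidy CSV export."""
    df = pd.read_csv(path)
    events = tuple(
        StimulusEvent(
            trial_index=int(r.trial),
            cycle_index=int(r.cycle),
            onset=float(r.onset_s),
            duration=float(r.duration_s),
            numerosity=float(r.numerosity),
            is_target=bool(r.is_target),
        )
        for r in df.itertuples()
    )
    last = events[-1]
    n_volumes = math.ceil((last.onset + last.duration + tail) / tr)
    return StimulusSequence(condition, events, tr, n_volumes, iti, ici, seed)


def stimulus_units(seq: StimulusSequence,
                   duration_axis: MagnitudeAxis = DURATION_AXIS,
                   numerosity_axis: MagnitudeAxis = NUMEROSITY_AXIS) -> np.ndarray:
    """(n_events, 2) array of event magnitudes in arbitrary units
    (duration, numerosity).  Values fixed outside the tested range (the
    baselines' irrelevant magnitude) are mapped without clamping so they
    keep their true off-range position on the unit axis.
    """
    d = np.array([e.duration for e in seq.events])
    n = np.array([e.numerosity for e in seq.events])

    def _unclamped(v, axis):
        return 100.0 * (np.log(v) - math.log(axis.physical_min)) / (
            math.log(axis.physical_max) - math.log(axis.physical_min)
        )

    return np.column_stack([_unclamped(d, duration_axis), _unclamped(n, numerosity_axis)])
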