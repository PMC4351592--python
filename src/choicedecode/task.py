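"""Data model for the directional-choice lever-press task.

A freely moving rat self-starts a trial by pressing a center ready lever,
which simultaneously turns on one of five cue lights (LL, L, C, R, RR).
The two response levers extend 2 s after cue onset; the rat then presses
one of them.  Trials are labelled by cue side and first response press:
``L-L`` / ``R-R`` are correct directional choices, ``L-R`` / ``R-L`` are
errors (cue side first, press side second).  Analysis windows are fixed
half-open intervals anchored to cue onset or to the first response press.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

LEFT = "left"
RIGHT = "right"

#: cue label -> analysis side ("C" is the center cue, not a directional trial)
CUE_TO_SIDE = {
    "LL": LEFT,
    "L": LEFT,
    "C": None,
    "R": RIGHT,
    "RR": RIGHT,
    "left": LEFT,
    "right": RIGHT,
}

TRIAL_CLASSES = ("L-L", "R-R", "L-R", "R-L")
CORRECT_CLASSES = ("L-L", "R-R")

#: minimum trials per correct class for a session to enter analysis
MIN_TRIALS_PER_CLASS = 20


class NonDirectionalCueError(ValueError):
    """Raised when a center-cue trial is passed to directional-choice analysis."""


def cue_direction(cue_side: str) -> str:
    """Collapse a cue label to 'left' or 'right'.

    Raises
    ------
    NonDirectionalCueError
        for the center cue ``C``.
    ValueError
        for unknown labels.
    """
    try:
        side = CUE_TO_SIDE[cue_side]
    except KeyError:
        raise ValueError(f"unknown cue side {cue_side!r}") from None
    if side is None:
        raise NonDirectionalCueError(
            "center cue: not a directional-choice trial"
        )
    return side


def classify_trial(cue_side: str, first_press_side: str) -> str:
    """Trial class from cue side and first response press.

    (left, left) -> 'L-L'; (right, right) -> 'R-R';
    (right, left) -> 'R-L'; (left, right) -> 'L-R'.
    """
    cue = cue_direction(cue_side)
    if first_press_side not in (LEFT, RIGHT):
        raise ValueError(f"unknown press side {first_press_side!r}")
    return f"{cue[0].upper()}-{first_press_side[0].upper()}"


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps (ms, session clock) of one isolated unit."""

    unit_id: int
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if ts.size and not np.all(np.isfinite(ts)):
            raise ValueError(f"unit {self.unit_id}: non-finite spike timestamp")
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            raise ValueError(f"unit {self.unit_id}: spike timestamps not sorted")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def count(self, start: float, end: float) -> int:
        """Spike count in the half-open interval [start, end)."""
        return int(
            np.searchsorted(self.timestamps, end, side="left")
            - np.searchsorted(self.timestamps, start, side="left")
        )


@dataclass(frozen=True)
class Trial:
    """One behavioral trial; timestamps in ms on the session clock.

    The cue turns on simultaneously with the ready press (t_cue == t_ready)
    and the response levers extend 2 s later.  ``t_press`` is the first
    response press (nan when the trial had none).
    """

    cue_side: str
    first_press_side: str
    t_ready: float
    t_cue: float
    t_extend: float
    t_press: float
    t_feedback: float
    outcome: str

    def __post_init__(self) -> None:
        if self.cue_side not in CUE_TO_SIDE:
            raise ValueError(f"unknown cue side {self.cue_side!r}")
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.t_cue != self.t_ready:
            raise ValueError("cue onset must coincide with the ready press")
        if self.t_extend != self.t_cue + 2000.0:
            raise ValueError("levers must extend 2000 ms after cue onset")
        if np.isfinite(self.t_press) and self.t_press < self.t_extend:
            raise ValueError("response press before lever extension")

    @property
    def trial_class(self) -> str | None:
        """'L-L' / 'R-R' / 'L-R' / 'R-L', or None for a center-cue trial."""
        try:
            return classify_trial(self.cue_side, self.first_press_side)
        except NonDirectionalCueError:
            return None

    @property
    def response_latency(self) -> float:
        """Lever extension to first press, seconds (nan if no press)."""
        return (self.t_press - self.t_extend) / 1000.0


class AnalysisWindow(NamedTuple):
    name: str
    anchor: str  # 'cue' or 'press'
    start: float  # ms relative to anchor
    end: float


#: Fixed window catalog.  BC: pre-cue baseline; CO: main cue-on window;
#: CO1-3: 500 ms cue-on sub-windows; LP: around the response press.
WINDOWS = {
    "BC": AnalysisWindow("BC", "cue", -500.0, 0.0),
    "CO": AnalysisWindow("CO", "cue", 300.0, 1800.0),
    "CO1": AnalysisWindow("CO1", "cue", 500.0, 1000.0),
    "CO2": AnalysisWindow("CO2", "cue", 1000.0, 1500.0),
    "CO3": AnalysisWindow("CO3", "cue", 1500.0, 2000.0),
    "LP": AnalysisWindow("LP", "press", -100.0, 400.0),
}


def window_bounds(window_name: str, trial: Trial) -> tuple[float, float]:
    """Absolute half-open interval [start, end) of a catalog window for a trial."""
    try:
        win = WINDOWS[window_name]
    except KeyError:
        raise ValueError(f"unknown analysis window {window_name!r}") from None
    if win.anchor == "cue":
        anchor = trial.t_cue
    else:
        anchor = trial.t_press
        if not np.isfinite(anchor):
            raise ValueError("LP window requested for a trial without a press")
    return (anchor + win.start, anchor + win.end)


@dataclass
class Session:
    """One recording day: trials plus simultaneously recorded spike trains."""

    session_index: int
    trials: list[Trial]
    spike_trains: list[SpikeTrain]
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        self.spike_trains = sorted(self.spike_trains, key=lambda s: s.unit_id)
        ids = [s.unit_id for s in self.spike_trains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids in session")

    @property
    def unit_ids(self) -> list[int]:
        return [s.unit_id for s in self.spike_trains]

    @property
    def n_units(self) -> int:
        return len(self.spike_trains)

    def spike_train(self, unit_id: int) -> SpikeTrain:
        for s in self.spike_trains:
            if s.unit_id == unit_id:
                return s
        raise KeyError(f"no unit {unit_id} in session {self.session_index}")

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(TRIAL_CLASSES, 0)
        for t in self.trials:
            c = t.trial_class
            if c is not None:
                counts[c] += 1
        return counts

    @property
    def behavioral_accuracy(self) -> float:
        """Fraction of successful trials."""
        if not self.trials:
            return float("nan")
        n_ok = sum(t.outcome == "success" for t in self.trials)
        return n_ok / len(self.trials)

    @property
    def included(self) -> bool:
        """Session enters analysis iff it has >=20 L-L and >=20 R-R trials."""
        counts = self.class_counts()
        return (
            counts["L-L"] >= MIN_TRIALS_PER_CLASS
            and counts["R-R"] >= MIN_TRIALS_PER_CLASS
        )


def select_trials(session: Session, classes: Iterable[str]) -> list[Trial]:
    """Trials of the requested classes, in chronological order."""
    wanted = set(classes)
    unknown = wanted - set(TRIAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown trial classes {sorted(unknown)}")
    picked = [t for t in session.trials if t.trial_class in wanted]
    return sorted(picked, key=lambda t: t.t_cue)


def filter_sessions(sessions: Sequence[Session]) -> list[Session]:
    """Sessions with at least 20 trials in each correct class."""
    return [s for s in sessions if s.included]
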