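"""Synthetic multi-session spike-train and behavior generator.

Emulates the statistical structure of chronic motor-cortical ensemble
recordings during directional-choice learning: a small fixed-size ensemble
(3-6 units) recorded over ~20 sessions, ~56 correct trials per class and
session, direction-dependent rate modulation emerging ~400 ms after cue
onset with a 2-3 Hz class difference, a behavioral accuracy curve rising
from ~31% to ~76%, and response latency stabilizing after the first three
sessions.

Two tuning regimes are available:

``rate_offset``
    The class difference lives in per-unit mean rates (half the units
    prefer left, half right), so both the per-unit rate difference and
    spatiotemporal decoders see signal.

``pattern_rotation``
    A fixed per-session difference budget is redistributed across units
    and time bins with zero sum, so the one-dimensional ensemble mean
    difference is ~0 while spatiotemporal spike-count patterns separate.
    This realizes the dissociation between flat ensemble-mean statistics
    and rising pattern discriminability.

Spikes are drawn as an inhomogeneous Poisson process with piecewise-
constant rate in 100 ms panels: a Poisson count per panel, spikes placed
uniformly within it.  Timestamps are rounded to integer ms so sessions
round-trip exactly through the CSV interchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import LEFT, RIGHT, Session, SpikeTrain, Trial

#: simulated peri-cue span per trial (ms relative to cue onset)
TRIAL_SPAN = (-1000.0, 3000.0)
PANEL_MS = 100.0
#: cue-on period (cue onset to lever extension)
CUE_ON_MS = 2000.0
#: spacing between consecutive cue onsets on the session clock
TRIAL_SPACING_MS = 12000.0
#: pattern_rotation difference blocks (ms after cue): +delta, -delta
ROTATION_POS_BLOCK = (400.0, 900.0)
ROTATION_NEG_BLOCK = (1300.0, 1800.0)


def make_learning_curve(
    n_sessions: int,
    start_acc: float,
    end_acc: float,
    latency_start: float,
    latency_end: float,
    rate_constant: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-session behavioral accuracy and mean response latency.

    Accuracy follows a saturating exponential pinned to ``start_acc`` at
    session 1 and ``end_acc`` at the last session.  Latency interpolates
    linearly from ``latency_start`` to ``latency_end`` over the first
    three session-to-session steps and is constant from session 4 on.

    Returns
    -------
    (accuracy, latency) : two arrays of length ``n_sessions``;
        accuracy is a fraction in [0, 1], latency in seconds.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions for a learning curve")
    if not (0.0 <= start_acc <= end_acc <= 1.0):
        raise ValueError(
            "accuracies must satisfy 0 <= start_acc <= end_acc <= 1, got "
            f"start={start_acc}, end={end_acc}"
        )
    if latency_start < 0 or latency_end < 0:
        raise ValueError("latencies must be nonnegative")
    u = np.linspace(0.0, 1.0, n_sessions)
    shape = -np.expm1(-rate_constant * u) / -np.expm1(-rate_constant)
    accuracy = np.clip(start_acc + (end_acc - start_acc) * shape, start_acc, end_acc)
    accuracy[0], accuracy[-1] = start_acc, end_acc

    k = np.arange(1, n_sessions + 1)
    knee = min(4, n_sessions)
    frac = np.clip((k - 1) / (knee - 1), 0.0, 1.0) if knee > 1 else np.ones_like(k, float)
    latency = latency_start + (latency_end - latency_start) * frac
    latency[k >= knee] = latency_end
    return accuracy, latency


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    ``tuning_amplitude_schedule`` is the per-session class-separation
    parameter d(k) in Hz (the mean class rate difference over the CO
    window in rate_offset mode; the per-bin pattern amplitude in
    pattern_rotation mode).  ``None`` means a constant 3 Hz, matching the
    2-3 Hz per-unit class differences seen in the cue-on sub-windows.
    """

    n_units: int = 4
    n_sessions: int = 21
    trials_per_class: int = 56
    baseline_rate: float = 10.0
    tuning_amplitude_schedule: tuple[float, ...] | None = None
    modulation_onset: float = 400.0
    mean_conservation: bool = True
    pattern_mode: str = "rate_offset"
    #: which side's tuning an error trial expresses: the chosen side
    #: ("choice") or the cued side ("cue")
    error_tuning: str = "choice"
    behavior_accuracy: tuple[float, ...] | None = None
    behavior_latency: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_class < 20:
            raise ValueError(
                "trials_per_class must be >= 20 (sessions below the "
                "20-trial inclusion threshold are excluded downstream)"
            )
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.pattern_mode not in ("rate_offset", "pattern_rotation"):
            raise ValueError(f"unknown pattern_mode {self.pattern_mode!r}")
        if self.error_tuning not in ("choice", "cue"):
            raise ValueError(f"unknown error_tuning {self.error_tuning!r}")
        if not 0.0 <= self.modulation_onset < CUE_ON_MS:
            raise ValueError("modulation_onset must lie in the cue-on period")
        if np.any(self.schedule() < 0):
            raise ValueError("tuning amplitudes d(k) must be >= 0")
        acc, _ = self.behavior()
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("behavioral accuracies must lie in [0, 1]")

    def schedule(self) -> np.ndarray:
        """d(k) per session, Hz."""
        if self.tuning_amplitude_schedule is None:
            return np.full(self.n_sessions, 3.0)
        sched = np.asarray(self.tuning_amplitude_schedule, dtype=float)
        if sched.shape != (self.n_sessions,):
            raise ValueError(
                f"tuning_amplitude_schedule must have length {self.n_sessions}"
            )
        return sched

    def behavior(self) -> tuple[np.ndarray, np.ndarray]:
        """(accuracy, latency) per session."""
        if self.behavior_accuracy is None or self.behavior_latency is None:
            if self.n_sessions == 1:
                return np.array([0.308]), np.array([0.44])
            acc, lat = make_learning_curve(self.n_sessions, 0.308, 0.760, 0.44, 0.32)
        else:
            acc = np.asarray(self.behavior_accuracy, dtype=float)
            lat = np.asarray(self.behavior_latency, dtype=float)
        if acc.shape != (self.n_sessions,) or lat.shape != (self.n_sessions,):
            raise ValueError("behavior curves must have one value per session")
        return acc, lat


@dataclass(frozen=True)
class TuningProfile:
    """Piecewise-constant per-unit rate functions for the two trial classes.

    ``edges`` are panel edges in ms relative to cue onset; ``rate_left``
    and ``rate_right`` are (n_units, n_panels) arrays in Hz giving the
    rate on left-choice and right-choice trials.
    """

    edges: np.ndarray
    rate_left: np.ndarray
    rate_right: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.rate_left, self.rate_right):
            if np.any(arr < 0):
                raise ValueError("rates must be nonnegative everywhere")
            if arr.shape != (self.rate_left.shape[0], self.edges.size - 1):
                raise ValueError("rate array shape inconsistent with edges")

    @property
    def n_units(self) -> int:
        return self.rate_left.shape[0]

    def grand_mean_rate(self) -> float:
        """Mean of (rate_left + rate_right)/2 over units and panels, Hz."""
        return float(np.mean((self.rate_left + self.rate_right) / 2.0))


def _panel_grid() -> np.ndarray:
    start, end = TRIAL_SPAN
    return np.arange(start, end + PANEL_MS / 2, PANEL_MS)


def make_tuning_profiles(config: GeneratorConfig, session_index: int) -> TuningProfile:
    """Per-unit class rate functions for one session.

    rate_offset: all units fire more on left-choice trials (a shared
    population preference, so the pooled signed class difference is
    positive); the class difference is constant over [onset, 2000) ms
    and scaled so its mean over the CO window (300-1800 ms) equals d(k)
    per unit.  With
    ``mean_conservation`` the offsets are symmetric (+/- delta/2), so the
    class-averaged rate equals the baseline for every unit and session;
    otherwise the whole difference is added to left-choice trials, making
    the grand mean drift with d(k).

    pattern_rotation: the difference is +delta on 400-900 ms and -delta
    on 1300-1800 ms (sign alternating across units), which sums to zero
    over units and panels and also over the CO window's 500 ms bins,
    while single bins carry signal proportional to d(k).
    """
    if not 1 <= session_index <= config.n_sessions:
        raise ValueError(
            f"session_index {session_index} outside [1, {config.n_sessions}]"
        )
    d = float(config.schedule()[session_index - 1])
    edges = _panel_grid()
    centers = (edges[:-1] + edges[1:]) / 2.0
    n_panels = centers.size
    base = np.full((config.n_units, n_panels), config.baseline_rate)
    diff = np.zeros_like(base)  # rate_left - rate_right per unit and panel

    unit_sign = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(config.n_units)])

    if config.pattern_mode == "rate_offset":
        # CO window [300, 1800) overlaps the modulated span [onset, 2000)
        # over (1800 - onset) ms out of 1500; rescale so the CO-window mean
        # class difference equals d exactly.
        overlap = 1800.0 - config.modulation_onset
        if overlap <= 0:
            raise ValueError("modulation_onset must precede the CO window end")
        delta = d * 1500.0 / overlap
        in_mod = (centers >= config.modulation_onset) & (centers < CUE_ON_MS)
        # population-level preference: all units fire more on left-choice
        # trials, matching the positive pooled class difference
        diff[:, in_mod] = delta
        if config.mean_conservation:
            rate_left = base + diff / 2.0
            rate_right = base - diff / 2.0
        else:
            rate_left = base + np.abs(diff)  # all of the difference on one class
            rate_right = base + np.abs(diff) - diff
    else:  # pattern_rotation
        if config.modulation_onset > ROTATION_POS_BLOCK[0]:
            raise ValueError(
                "pattern_rotation requires modulation_onset <= "
                f"{ROTATION_POS_BLOCK[0]:.0f} ms"
            )
        pos = (centers >= ROTATION_POS_BLOCK[0]) & (centers < ROTATION_POS_BLOCK[1])
        neg = (centers >= ROTATION_NEG_BLOCK[0]) & (centers < ROTATION_NEG_BLOCK[1])
        diff[:, pos] = (unit_sign * d)[:, None]
        diff[:, neg] = -(unit_sign * d)[:, None]
        rate_left = base + diff / 2.0
        rate_right = base - diff / 2.0

    if np.any(rate_left < 0) or np.any(rate_right < 0):
        raise ValueError(
            "tuning would produce negative rates; raise baseline_rate or lower d(k)"
        )
    return TuningProfile(edges=edges, rate_left=rate_left, rate_right=rate_right)


def _draw_trial_spikes(
    rates_hz: np.ndarray, edges: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes (ms re cue) for one unit and trial."""
    widths_s = np.diff(edges) / 1000.0
    counts = rng.poisson(rates_hz * widths_s)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    spikes = np.concatenate(
        [
            rng.uniform(edges[j], edges[j + 1], size=c)
            for j, c in enumerate(counts)
            if c > 0
        ]
    )
    return np.sort(spikes)


def simulate_session(
    config: GeneratorConfig,
    session_index: int,
    rng: np.random.Generator | None = None,
) -> Session:
    """Generate one session: trials, outcomes, and ensemble spike trains.

    Correct trials number ``trials_per_class`` per class; error trials
    (first press opposite the cue) are added so the session's behavioral
    accuracy approximates the learning curve at this session.  The RNG
    defaults to the documented subseed stream ``default_rng([seed, k])``
    so any session is reproducible in isolation.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, session_index])
    profile = make_tuning_profiles(config, session_index)
    acc_curve, lat_curve = config.behavior()
    acc = float(acc_curve[session_index - 1])
    lat = float(lat_curve[session_index - 1])

    n_correct = 2 * config.trials_per_class
    n_error = int(round(n_correct * (1.0 - acc) / acc)) if acc > 0 else 0
    specs: list[tuple[str, str]] = []  # (cue direction, press direction)
    specs += [(LEFT, LEFT)] * config.trials_per_class
    specs += [(RIGHT, RIGHT)] * config.trials_per_class
    for j in range(n_error):
        cue = LEFT if j % 2 == 0 else RIGHT
        specs.append((cue, RIGHT if cue == LEFT else LEFT))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    trials: list[Trial] = []
    per_unit_spikes: list[list[np.ndarray]] = [[] for _ in range(config.n_units)]
    for i, (cue_dir, press_dir) in enumerate(specs):
        t_cue = 5000.0 + i * TRIAL_SPACING_MS
        latency_s = float(np.clip(rng.normal(lat, 0.15), 0.05, 1.0))
        t_press = t_cue + CUE_ON_MS + round(latency_s * 1000.0)
        cue_label = str(rng.choice(["LL", "L"] if cue_dir == LEFT else ["R", "RR"]))
        outcome = "success" if cue_dir == press_dir else "failure"
        trials.append(
            Trial(
                cue_side=cue_label,
                first_press_side=press_dir,
                t_ready=t_cue,
                t_cue=t_cue,
                t_extend=t_cue + CUE_ON_MS,
                t_press=t_press,
                t_feedback=t_press + 1000.0,
                outcome=outcome,
            )
        )
        tuned_side = press_dir if config.error_tuning == "choice" else cue_dir
        rates = profile.rate_left if tuned_side == LEFT else profile.rate_right
        for u in range(config.n_units):
            spikes = _draw_trial_spikes(rates[u], profile.edges, rng)
            if spikes.size:
                per_unit_spikes[u].append(np.round(spikes + t_cue))

    spike_trains = [
        SpikeTrain(
            unit_id=u + 1,
            timestamps=np.sort(np.concatenate(per_unit_spikes[u]))
            if per_unit_spikes[u]
            else np.empty(0),
        )
        for u in range(config.n_units)
    ]
    return Session(
        session_index=session_index,
        trials=trials,
        spike_trains=spike_trains,
        subject_id="sim",
    )


def simulate_experiment(config: GeneratorConfig) -> list[Session]:
    """All sessions of one synthetic subject, each from its own subseed."""
    return [
        simulate_session(config, k) for k in range(1, config.n_sessions + 1)
    ]
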