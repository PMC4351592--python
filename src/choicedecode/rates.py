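"""Firing-rate estimation and ensemble rate statistics.

Single-trial rates use a 100 ms boxcar window sliding in 20 ms steps
(50 estimates per second).  Session-level summaries follow the ensemble
conventions: per unit i and session k, M_L^i and M_R^i are the class-mean
window rates, M^i = (M_L^i + M_R^i)/2, D^i = M_L^i - M_R^i; the ensemble
mean rate is M(k) = mean_i M^i(k) and the ensemble mean rate difference
is D(k) = mean_i |D^i(k)|.  S_L^i / S_R^i are across-trial standard
deviations, averaged over units into S_L(k) / S_R(k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import Session, SpikeTrain, Trial, WINDOWS, select_trials, window_bounds

DEFAULT_BIN_MS = 100.0
DEFAULT_STEP_MS = 20.0


@dataclass(frozen=True)
class RateSeries:
    """Sliding firing-rate estimate: bin centers (ms) and rates (Hz)."""

    times: np.ndarray
    values: np.ndarray
    bin_width: float
    step: float


def _window_centers(start: float, end: float, step: float) -> np.ndarray:
    n = int(round((end - start) / step))
    return start + step * np.arange(n)


def sliding_rate(
    spike_train: SpikeTrain | np.ndarray,
    interval: tuple[float, float],
    bin_width: float = DEFAULT_BIN_MS,
    step: float = DEFAULT_STEP_MS,
) -> RateSeries:
    """Boxcar sliding-window rate over ``interval`` = [start, end).

    Window centers sit on the step grid starting at the interval start,
    so a 1 s interval at 20 ms steps yields exactly 50 estimates; each
    value is the spike count in [t - bin_width/2, t + bin_width/2)
    divided by the window length.
    """
    if bin_width <= 0 or step <= 0:
        raise ValueError("bin_width and step must be positive")
    ts = (
        spike_train.timestamps
        if isinstance(spike_train, SpikeTrain)
        else np.asarray(spike_train, dtype=float)
    )
    start, end = interval
    if end <= start:
        raise ValueError("empty interval")
    centers = _window_centers(start, end, step)
    lo = np.searchsorted(ts, centers - bin_width / 2.0, side="left")
    hi = np.searchsorted(ts, centers + bin_width / 2.0, side="left")
    values = (hi - lo) / (bin_width / 1000.0)
    return RateSeries(times=centers, values=values, bin_width=bin_width, step=step)


def _trial_rate_matrix(
    trials: Sequence[Trial],
    train: SpikeTrain,
    anchor: str,
    rel_interval: tuple[float, float],
    bin_width: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_trials, n_bins) sliding rates anchored per trial; returns (times, rates)."""
    rows = []
    times = None
    for t in trials:
        t0 = t.t_cue if anchor == "cue" else t.t_press
        series = sliding_rate(
            train, (t0 + rel_interval[0], t0 + rel_interval[1]), bin_width, step
        )
        rows.append(series.values)
        times = series.times - t0
    return times, np.asarray(rows)


def peth(
    trials_by_class: dict[str, Sequence[Trial]],
    train: SpikeTrain,
    anchor: str = "cue",
    rel_interval: tuple[float, float] = (-500.0, 2000.0),
    bin_width: float = DEFAULT_BIN_MS,
    step: float = DEFAULT_STEP_MS,
    alpha: float = 0.01,
) -> dict:
    """Peri-event time histogram per class with per-bin rank-sum flags.

    Returns a dict with 'times' (ms re anchor), 'mean' (class -> mean
    RateSeries values), and, when exactly two classes are given,
    'p_values' and 'significant' from a per-bin two-sided rank-sum test
    at ``alpha``.
    """
    for cls, trials in trials_by_class.items():
        if len(trials) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
    mats = {}
    times = None
    for cls, trials in trials_by_class.items():
        times, mat = _trial_rate_matrix(
            trials, train, anchor, rel_interval, bin_width, step
        )
        mats[cls] = mat
    out = {
        "times": times,
        "mean": {cls: mat.mean(axis=0) for cls, mat in mats.items()},
    }
    if len(mats) == 2:
        a, b = (mats[c] for c in mats)
        p = np.array(
            [stats.ranksums(a[:, j], b[:, j]).pvalue for j in range(a.shape[1])]
        )
        out["p_values"] = p
        out["significant"] = p < alpha
    return out


@dataclass(frozen=True)
class SessionRateSummary:
    """Per-unit and ensemble window-rate statistics for one session."""

    session_index: int
    window: str
    unit_ids: tuple[int, ...]
    m_left: np.ndarray  # M_L^i, Hz
    m_right: np.ndarray  # M_R^i
    s_left: np.ndarray  # S_L^i, across-trial SD
    s_right: np.ndarray

    @property
    def m_unit(self) -> np.ndarray:
        """M^i = (M_L^i + M_R^i) / 2."""
        return (self.m_left + self.m_right) / 2.0

    @property
    def d_unit(self) -> np.ndarray:
        """D^i = M_L^i - M_R^i."""
        return self.m_left - self.m_right

    @property
    def ensemble_mean_rate(self) -> float:
        """M(k): mean over units of M^i."""
        return float(np.mean(self.m_unit))

    @property
    def ensemble_rate_difference(self) -> float:
        """D(k): mean over units of |D^i|."""
        return float(np.mean(np.abs(self.d_unit)))

    @property
    def ensemble_signed_difference(self) -> float:
        """Mean over units of D^i (no absolute value)."""
        return float(np.mean(self.d_unit))

    @property
    def s_ensemble_left(self) -> float:
        return float(np.mean(self.s_left))

    @property
    def s_ensemble_right(self) -> float:
        return float(np.mean(self.s_right))

    def to_frame(self) -> pd.DataFrame:
        """One row per unit plus one ensemble row."""
        rows = []
        for j, uid in enumerate(self.unit_ids):
            rows.append(
                {
                    "session_index": self.session_index,
                    "window": self.window,
                    "unit_id": uid,
                    "m_left_hz": self.m_left[j],
                    "m_right_hz": self.m_right[j],
                    "m_unit_hz": self.m_unit[j],
                    "d_unit_hz": self.d_unit[j],
                    "s_left_hz": self.s_left[j],
                    "s_right_hz": self.s_right[j],
                }
            )
        rows.append(
            {
                "session_index": self.session_index,
                "window": self.window,
                "unit_id": "ensemble",
                "m_left_hz": float(np.mean(self.m_left)),
                "m_right_hz": float(np.mean(self.m_right)),
                "m_unit_hz": self.ensemble_mean_rate,
                "d_unit_hz": self.ensemble_rate_difference,
                "s_left_hz": self.s_ensemble_left,
                "s_right_hz": self.s_ensemble_right,
            }
        )
        return pd.DataFrame(rows)


def window_mean_rates(
    trials: Sequence[Trial],
    train: SpikeTrain,
    window: str,
    bin_width: float = DEFAULT_BIN_MS,
    step: float = DEFAULT_STEP_MS,
) -> np.ndarray:
    """Per-trial mean rate: average of the sliding-bin rates in the window."""
    out = np.empty(len(trials))
    for i, t in enumerate(trials):
        series = sliding_rate(train, window_bounds(window, t), bin_width, step)
        out[i] = series.values.mean()
    return out


def unit_and_ensemble_summary(session: Session, window: str) -> SessionRateSummary:
    """Class-mean rates, differences and variabilities for one session."""
    if window not in WINDOWS:
        raise ValueError(f"unknown analysis window {window!r}")
    left = select_trials(session, ["L-L"])
    right = select_trials(session, ["R-R"])
    m_l, m_r, s_l, s_r = [], [], [], []
    for train in session.spike_trains:
        rl = window_mean_rates(left, train, window)
        rr = window_mean_rates(right, train, window)
        m_l.append(rl.mean())
        m_r.append(rr.mean())
        s_l.append(rl.std(ddof=1) if rl.size > 1 else 0.0)
        s_r.append(rr.std(ddof=1) if rr.size > 1 else 0.0)
    return SessionRateSummary(
        session_index=session.session_index,
        window=window,
        unit_ids=tuple(session.unit_ids),
        m_left=np.asarray(m_l),
        m_right=np.asarray(m_r),
        s_left=np.asarray(s_l),
        s_right=np.asarray(s_r),
    )


def summary_table(sessions: Sequence[Session], window: str) -> pd.DataFrame:
    """Concatenated per-session summary rows (units + ensemble)."""
    return pd.concat(
        [unit_and_ensemble_summary(s, window).to_frame() for s in sessions],
        ignore_index=True,
    )


def time_resolved_difference(
    sessions: Sequence[Session],
    rel_interval: tuple[float, float] = (-500.0, 2000.0),
    bin_width: float = DEFAULT_BIN_MS,
    step: float = DEFAULT_STEP_MS,
    alpha: float = 0.001,
) -> dict:
    """Pooled time-resolved class rate difference with per-bin t-tests.

    Each unit-session record contributes one difference series (trial-mean
    left-choice rate minus trial-mean right-choice rate, cue-aligned);
    records are pooled as independent samples and each bin is tested
    against zero with a one-sample t-test at ``alpha``.
    """
    records = []
    times = None
    for session in sessions:
        left = select_trials(session, ["L-L"])
        right = select_trials(session, ["R-R"])
        for train in session.spike_trains:
            times, mat_l = _trial_rate_matrix(
                left, train, "cue", rel_interval, bin_width, step
            )
            _, mat_r = _trial_rate_matrix(
                right, train, "cue", rel_interval, bin_width, step
            )
            records.append(mat_l.mean(axis=0) - mat_r.mean(axis=0))
    if len(records) < 2:
        raise ValueError("need at least 2 unit-session records")
    pooled = np.asarray(records)
    res = stats.ttest_1samp(pooled, 0.0, axis=0)
    return {
        "times": times,
        "mean_difference": pooled.mean(axis=0),
        "p_values": res.pvalue,
        "significant": res.pvalue < alpha,
        "n_records": pooled.shape[0],
    }


def zscore_over_sessions(values: Sequence[float]) -> np.ndarray:
    """Standardize a per-session measure to mean 0 and sample SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to Z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot Z-score values with zero spread")
    return (x - x.mean()) / sd
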