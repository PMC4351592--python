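"""Session-trend statistics for learning-related change.

Session-wise measures (ensemble mean rate, rate difference, decoding
accuracy, class distance) are Z-scored per subject, regressed against
normalized session number (first session -> 0, last -> 1) by ordinary
least squares, and the slope's sign is called from its confidence
interval (99% by default): positive if the whole interval is above
zero, negative if below, otherwise zero.  Complementary summaries
divide the learning process into equal-length stages and compare stage
means by one-way ANOVA, and an ANCOVA-style interaction test compares
the slopes of two measures on a common axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .task import Session


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope with confidence interval and CI-based sign call."""

    slope: float
    intercept: float
    ci_level: float
    ci: tuple[float, float]

    @property
    def sign_call(self) -> str:
        lo, hi = self.ci
        if lo > 0:
            return "positive"
        if hi < 0:
            return "negative"
        return "zero"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_level": self.ci_level,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "sign_call": self.sign_call,
        }


def normalize_sessions(indices: Sequence[float]) -> np.ndarray:
    """Affine map of session indices to [0, 1] (first -> 0, last -> 1)."""
    x = np.asarray(indices, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct session indices")
    return (x - x.min()) / (x.max() - x.min())


def slope_with_ci(
    y: Sequence[float], x: Sequence[float], level: float = 0.99
) -> RegressionResult:
    """Ordinary least-squares slope of y on x with a t-based CI."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need matched x and y with at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + level / 2.0, y.size - 2)
    half = tcrit * res.stderr
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_level=level,
        ci=(float(res.slope - half), float(res.slope + half)),
    )


@dataclass(frozen=True)
class StageSummary:
    """Means/SDs of a session-wise measure in contiguous learning stages."""

    n_stages: int
    stage_slices: tuple[tuple[int, int], ...]
    means: np.ndarray
    sds: np.ndarray
    p_values: dict[str, float]  # pairwise one-way ANOVA, e.g. "1_vs_3"

    def to_dict(self) -> dict:
        return {
            "n_stages": self.n_stages,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "p_values": self.p_values,
        }


def stage_partition(n: int, n_stages: int = 3) -> list[tuple[int, int]]:
    """Contiguous equal-length stages; remainder sessions go to the last stages."""
    if n < n_stages:
        raise ValueError(f"cannot split {n} sessions into {n_stages} stages")
    base, rem = divmod(n, n_stages)
    sizes = [base] * n_stages
    for j in range(rem):  # extra sessions to the LAST stage(s)
        sizes[n_stages - 1 - j] += 1
    bounds, start = [], 0
    for size in sizes:
        bounds.append((start, start + size))
        start += size
    return bounds


def stage_summary(values: Sequence[float], n_stages: int = 3) -> StageSummary:
    """Stage means, SDs, and pairwise one-way ANOVA p-values."""
    v = np.asarray(values, dtype=float)
    slices = stage_partition(v.size, n_stages)
    groups = [v[a:b] for a, b in slices]
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) if g.size > 1 else 0.0 for g in groups])
    p_values = {}
    for i in range(n_stages):
        for j in range(i + 1, n_stages):
            p = float(stats.f_oneway(groups[i], groups[j]).pvalue)
            p_values[f"{i + 1}_vs_{j + 1}"] = p
    return StageSummary(
        n_stages=n_stages,
        stage_slices=tuple(slices),
        means=means,
        sds=sds,
        p_values=p_values,
    )


def accuracy_vs_behavior_regression(
    decoding_accuracy: dict[str, Sequence[float]] | Sequence[float],
    behavior_accuracy: dict[str, Sequence[float]] | Sequence[float],
    level: float = 0.99,
) -> tuple[dict[str, RegressionResult], float | None]:
    """Per-subject regression of decoding accuracy on behavioral accuracy.

    Accepts either plain per-session sequences (treated as one subject)
    or dicts keyed by subject id.  Returns per-subject results and, when
    at least two subjects are available, the p-value of a one-sample
    t-test of the subject slopes against zero (None otherwise).
    """
    if not isinstance(decoding_accuracy, dict):
        decoding_accuracy = {"subject": decoding_accuracy}
        behavior_accuracy = {"subject": behavior_accuracy}
    if set(decoding_accuracy) != set(behavior_accuracy):
        raise ValueError("decoding and behavior dicts must share subjects")
    per_subject = {
        subj: slope_with_ci(decoding_accuracy[subj], behavior_accuracy[subj], level)
        for subj in sorted(decoding_accuracy)
    }
    slopes = [r.slope for r in per_subject.values()]
    p_across = (
        float(stats.ttest_1samp(slopes, 0.0).pvalue) if len(slopes) >= 2 else None
    )
    return per_subject, p_across


def slope_comparison(
    series_a: Sequence[float],
    series_b: Sequence[float],
    common_x: Sequence[float],
) -> float:
    """ANCOVA-style test for unequal slopes of two series on a common axis.

    Fits y ~ x + group + x:group over the stacked data and returns the
    p-value of the interaction coefficient.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    x = np.asarray(common_x, dtype=float)
    if a.size != x.size or b.size != x.size or x.size < 3:
        raise ValueError("series must match common_x with at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("common_x must not be constant")
    y = np.concatenate([a, b])
    xx = np.concatenate([x, x])
    g = np.concatenate([np.zeros_like(x), np.ones_like(x)])
    design = sm.add_constant(np.column_stack([xx, g, xx * g]))
    fit = sm.OLS(y, design).fit()
    return float(fit.pvalues[-1])


@dataclass(frozen=True)
class BehaviorSummary:
    """Behavioral learning summary across sessions."""

    accuracy: np.ndarray  # per session
    latency_mean: np.ndarray  # per session, s
    latency_sd: np.ndarray
    first_vs_last_p: float  # rank-sum on per-trial outcomes
    early_latency_p: float | None  # ANOVA over sessions 1..4 per-trial latencies
    late_latency_regression: RegressionResult | None  # from session 4 on, s/session

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.tolist(),
            "latency_mean_s": self.latency_mean.tolist(),
            "latency_sd_s": self.latency_sd.tolist(),
            "first_vs_last_p": self.first_vs_last_p,
            "early_latency_p": self.early_latency_p,
            "late_latency_regression": (
                self.late_latency_regression.to_dict()
                if self.late_latency_regression
                else None
            ),
        }


def behavior_summary(sessions: Sequence[Session], level: float = 0.99) -> BehaviorSummary:
    """Accuracy curve, latency stability, and first-vs-last comparison.

    The first-vs-last test rank-sums per-trial success indicators of the
    first and last sessions; the latency regression uses per-session
    mean latencies against raw session index from session 4 onward (the
    slope is in s/session).
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    sessions = sorted(sessions, key=lambda s: s.session_index)
    accuracy = np.array([s.behavioral_accuracy for s in sessions])

    def latencies(s: Session) -> np.ndarray:
        lat = np.array([t.response_latency for t in s.trials])
        return lat[np.isfinite(lat)]

    lat_mean = np.array([latencies(s).mean() for s in sessions])
    lat_sd = np.array(
        [latencies(s).std(ddof=1) if len(latencies(s)) > 1 else 0.0 for s in sessions]
    )

    def outcomes(s: Session) -> np.ndarray:
        return np.array([t.outcome == "success" for t in s.trials], dtype=float)

    first_vs_last_p = float(
        stats.ranksums(outcomes(sessions[0]), outcomes(sessions[-1])).pvalue
    )

    early = [latencies(s) for s in sessions[: min(4, len(sessions))]]
    early_p = float(stats.f_oneway(*early).pvalue) if len(early) >= 2 else None

    late = sessions[3:]
    late_reg = None
    if len(late) >= 3:
        late_reg = slope_with_ci(
            [latencies(s).mean() for s in late],
            [s.session_index for s in late],
            level,
        )
    return BehaviorSummary(
        accuracy=accuracy,
        latency_mean=lat_mean,
        latency_sd=lat_sd,
        first_vs_last_p=first_vs_last_p,
        early_latency_p=early_p,
        late_latency_regression=late_reg,
    )
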