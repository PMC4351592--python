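"""Spatiotemporal decoding of directional choice from spike-count vectors.

The sample for one trial is the concatenation (unit-major, ascending
unit id) of each unit's spike counts in non-overlapping bins of an
analysis window.  Discrimination uses a linear classifier trained on
trial-averaged samples: each training sample is the mean of ``n_average``
same-class single-trial vectors, while test samples are raw single-trial
vectors.  The session-level protocol repeats the whole
draw/split/average/train/test cycle ``n_repeats`` times (100 by default)
and averages test accuracy; the discriminability metric is the distance
between the class-mean decision-function values of test samples.

The classifier follows the sign convention df(x) >= 0 -> left-choice
class, df(x) < 0 -> right-choice class, with df the linear decision
function w.x + b (equivalently sum_i alpha_i K(s_i, x) + b over support
vectors for the SVM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .task import Session, Trial, WINDOWS, select_trials, window_bounds

CLASSIFIER_KINDS = ("svm_linear", "lda")


# ---------------------------------------------------------------------------
# feature construction


def spike_count_vector(
    trial: Trial,
    spike_trains: Sequence,
    window: str = "CO",
    bin_size: float = 500.0,
    allow_truncation: bool = False,
) -> np.ndarray:
    """Concatenated per-unit binned spike counts for one trial.

    Bins are half-open and tile the window; ``bin_size`` must divide the
    window length unless ``allow_truncation`` is set, in which case the
    trailing remainder is dropped.  Units are concatenated in ascending
    unit-id order, all bins of a unit contiguous.
    """
    start, end = window_bounds(window, trial)
    edges = _bin_edges(start, end, bin_size, allow_truncation)
    trains = sorted(spike_trains, key=lambda s: s.unit_id)
    counts = [np.histogram(tr.timestamps, bins=edges)[0] for tr in trains]
    return np.concatenate(counts).astype(float)


def _bin_edges(
    start: float, end: float, bin_size: float, allow_truncation: bool
) -> np.ndarray:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    length = end - start
    n_bins = int(math.floor(length / bin_size + 1e-9))
    if n_bins < 1:
        raise ValueError(f"bin_size {bin_size} larger than window length {length}")
    if not allow_truncation and abs(n_bins * bin_size - length) > 1e-6:
        raise ValueError(
            f"bin_size {bin_size} ms does not divide the {length:.0f} ms window; "
            "pass allow_truncation=True to drop the remainder"
        )
    return start + bin_size * np.arange(n_bins + 1)


def spike_count_matrix(
    session: Session,
    trials: Sequence[Trial],
    window: str = "CO",
    bin_size: float = 500.0,
    allow_truncation: bool = False,
) -> np.ndarray:
    """(n_trials, n_units * n_bins) spike-count samples."""
    return np.array(
        [
            spike_count_vector(
                t, session.spike_trains, window, bin_size, allow_truncation
            )
            for t in trials
        ]
    )


def unit_columns(n_units: int, n_bins: int, unit_pos: int | Sequence[int]) -> np.ndarray:
    """Column indices of one or more units in a unit-major concatenation."""
    pos = np.atleast_1d(unit_pos)
    return np.concatenate([np.arange(p * n_bins, (p + 1) * n_bins) for p in pos])


# ---------------------------------------------------------------------------
# estimator


def make_training_samples(
    raw_by_class: dict[str, np.ndarray],
    n_average: int,
    count_per_class: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged training set.

    Each sample is the arithmetic mean of ``n_average`` distinct raw
    same-class vectors (drawn without replacement per sample); its label
    is inherited.  ``count_per_class=None`` keeps the training-set size
    equal to the raw set per class.
    """
    xs, ys = [], []
    for label, raw in raw_by_class.items():
        raw = np.asarray(raw, dtype=float)
        if raw.shape[0] < n_average:
            raise ValueError(
                f"class {label!r} has {raw.shape[0]} raw training trials, "
                f"fewer than n_average={n_average}"
            )
        if n_average == 1 and count_per_class is None:
            # degenerate averaging: the raw vectors themselves
            xs.extend(raw)
            ys.extend([label] * raw.shape[0])
            continue
        n_out = raw.shape[0] if count_per_class is None else count_per_class
        for _ in range(n_out):
            idx = rng.choice(raw.shape[0], size=n_average, replace=False)
            xs.append(raw[idx].mean(axis=0))
            ys.append(label)
    return np.asarray(xs), np.asarray(ys)


class TrialAveragedLinearDecoder(ClassifierMixin, BaseEstimator):
    """Linear two-class decoder trained on trial-averaged spike-count vectors.

    Parameters
    ----------
    kind : {'svm_linear', 'lda'}
        Linear-kernel support vector machine or linear discriminant
        analysis.
    C : float
        SVM regularization constant (ignored for LDA).
    n_average : int
        Number of raw same-class vectors averaged into each training
        sample; ``1`` trains on raw (resampled) vectors.
    count_per_class : int or None
        Averaged training samples per class; ``None`` keeps the raw
        per-class training-set size.
    positive_label
        The class mapped to df >= 0 (the left-choice class by
        convention).
    random_state : int, sequence of int, Generator, or None
        Seed for the averaging draws.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    coef_, intercept_ : expanded linear form; ``decision_function`` is
        coef_ . x + intercept_, oriented so positive values mean
        ``positive_label``.
    """

    def __init__(
        self,
        kind: str = "svm_linear",
        C: float = 1.0,
        n_average: int = 5,
        count_per_class: int | None = None,
        positive_label="L-L",
        random_state=None,
    ):
        self.kind = kind
        self.C = C
        self.n_average = n_average
        self.count_per_class = count_per_class
        self.positive_label = positive_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        labels = sorted(set(y.tolist()))
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 classes, got {labels}")
        if self.positive_label not in labels:
            raise ValueError(
                f"positive_label {self.positive_label!r} not among classes {labels}"
            )
        negative = next(l for l in labels if l != self.positive_label)
        self.classes_ = np.array([negative, self.positive_label])
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        raw_by_class = {label: X[y == label] for label in labels}
        X_train, y_train = make_training_samples(
            raw_by_class, self.n_average, self.count_per_class, rng
        )
        # encode positive_label as 1 so sklearn's decision_function is
        # positive for it
        y01 = (y_train == self.positive_label).astype(int)
        if self.kind == "svm_linear":
            base = SVC(kernel="linear", C=self.C)
        else:
            base = LinearDiscriminantAnalysis()
        base.fit(X_train, y01)
        self.base_ = base
        self.coef_ = np.asarray(base.coef_, dtype=float).ravel()
        self.intercept_ = float(np.asarray(base.intercept_).ravel()[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """df(x) = w.x + b; df >= 0 means the positive (left-choice) class."""
        check_is_fitted(self, "base_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"x has dimension {X.shape[1]}, classifier was trained on "
                f"{self.n_features_in_}"
            )
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        df = self.decision_function(X)
        return np.where(df >= 0, self.classes_[1], self.classes_[0])

    def dual_decision_function(self, X) -> np.ndarray:
        """sum_i alpha_i K(s_i, x) + b from the SVM dual form (svm_linear only)."""
        check_is_fitted(self, "base_")
        if self.kind != "svm_linear":
            raise ValueError("dual form only available for the linear SVM")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sv = self.base_.support_vectors_
        alpha = self.base_.dual_coef_.ravel()
        return X @ sv.T @ alpha + self.intercept_


def classify(decoder: TrialAveragedLinearDecoder, x) -> tuple[str, float]:
    """Class label and decision-function value for one sample."""
    df = float(decoder.decision_function(np.atleast_2d(x))[0])
    label = decoder.classes_[1] if df >= 0 else decoder.classes_[0]
    return label, df


# ---------------------------------------------------------------------------
# resampled protocol


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the resampled decoding protocol."""

    n_repeats: int = 100
    test_fraction: float = 0.2
    n_average: int = 5
    trials_per_class: int | None = None  # None -> min class count per session
    bin_size: float = 500.0
    window: str = "CO"
    classifier_kind: str = "svm_linear"
    C: float = 1.0
    count_per_class: int | None = None  # averaged training samples; None -> raw size
    allow_truncation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_average < 1 or self.n_repeats < 1:
            raise ValueError("n_average and n_repeats must be >= 1")
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.classifier_kind!r}")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown analysis window {self.window!r}")


@dataclass(frozen=True)
class DecodingResult:
    """Outcome of one resampled decoding run."""

    classes: tuple[str, str]  # (positive, negative)
    accuracies: np.ndarray  # per repeat
    df_positive: np.ndarray  # test-sample df values, true positive class, pooled
    df_negative: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def class_distance(self) -> float:
        """Difference of class-mean decision-function values on test samples."""
        return float(self.df_positive.mean() - self.df_negative.mean())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "mean_accuracy": self.mean_accuracy,
            "class_distance": self.class_distance,
            "accuracies": self.accuracies.tolist(),
        }


def resampled_decoding(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    config: ProtocolConfig,
    classes: tuple[str, str] = ("L-L", "R-R"),
    shuffle: bool = False,
) -> DecodingResult:
    """Core repeated draw/split/average/train/test cycle on sample arrays.

    Per repeat r (RNG stream ``[seed, r]``): a constant number of trials
    is drawn without replacement from each class; ceil(test_fraction *
    n) of them form the test set and the rest the raw training set,
    which is turned into trial-averaged training samples before fitting.
    With ``shuffle`` the averaged training samples' class labels are
    permuted (stream ``[seed, r, 1]``) before fitting; test labels are
    untouched.
    """
    X_pos = np.asarray(X_pos, dtype=float)
    X_neg = np.asarray(X_neg, dtype=float)
    n = config.trials_per_class or min(X_pos.shape[0], X_neg.shape[0])
    if n > min(X_pos.shape[0], X_neg.shape[0]):
        raise ValueError(
            f"trials_per_class={n} exceeds available trials "
            f"({X_pos.shape[0]} vs {X_neg.shape[0]})"
        )
    n_test = math.ceil(config.test_fraction * n)
    n_train = n - n_test
    if n_train < config.n_average:
        raise ValueError(
            f"raw training set of {n_train} trials per class cannot support "
            f"{config.n_average}-trial averaging"
        )
    pos_label, neg_label = classes
    accuracies = np.empty(config.n_repeats)
    df_pos_all, df_neg_all = [], []
    for r in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, r])
        idx_p = rng.choice(X_pos.shape[0], size=n, replace=False)
        idx_n = rng.choice(X_neg.shape[0], size=n, replace=False)
        test_p, train_p = X_pos[idx_p[:n_test]], X_pos[idx_p[n_test:]]
        test_n, train_n = X_neg[idx_n[:n_test]], X_neg[idx_n[n_test:]]

        X_train, y_train = make_training_samples(
            {pos_label: train_p, neg_label: train_n},
            config.n_average,
            config.count_per_class,
            rng,
        )
        if shuffle:
            rng_shuf = np.random.default_rng([config.seed, r, 1])
            y_train = y_train[rng_shuf.permutation(y_train.shape[0])]
            if len(set(y_train.tolist())) < 2:  # pragma: no cover - tiny sets only
                y_train = np.array(
                    [pos_label, neg_label] * (y_train.shape[0] // 2 + 1)
                )[: y_train.shape[0]]

        decoder = TrialAveragedLinearDecoder(
            kind=config.classifier_kind,
            C=config.C,
            n_average=1,  # averaging already applied above
            count_per_class=None,
            positive_label=pos_label,
            random_state=rng,
        )
        decoder.fit(X_train, y_train)
        df_p = decoder.decision_function(test_p)
        df_n = decoder.decision_function(test_n)
        correct = int(np.sum(df_p >= 0)) + int(np.sum(df_n < 0))
        accuracies[r] = correct / (2 * n_test)
        df_pos_all.append(df_p)
        df_neg_all.append(df_n)
    return DecodingResult(
        classes=classes,
        accuracies=accuracies,
        df_positive=np.concatenate(df_pos_all),
        df_negative=np.concatenate(df_neg_all),
    )


def _class_matrices(
    session: Session,
    config: ProtocolConfig,
    classes: tuple[str, str] = ("L-L", "R-R"),
) -> tuple[np.ndarray, np.ndarray]:
    trials_pos = select_trials(session, [classes[0]])
    trials_neg = select_trials(session, [classes[1]])
    X_pos = spike_count_matrix(
        session, trials_pos, config.window, config.bin_size, config.allow_truncation
    )
    X_neg = spike_count_matrix(
        session, trials_neg, config.window, config.bin_size, config.allow_truncation
    )
    return X_pos, X_neg


def run_protocol(
    session: Session,
    config: ProtocolConfig,
    classes: tuple[str, str] = ("L-L", "R-R"),
) -> DecodingResult:
    """The full resampled decoding protocol on one session."""
    X_pos, X_neg = _class_matrices(session, config, classes)
    return resampled_decoding(X_pos, X_neg, config, classes)


def shuffle_control(
    session: Session,
    config: ProtocolConfig,
    classes: tuple[str, str] = ("L-L", "R-R"),
) -> DecodingResult:
    """Chance-level control: training-sample labels permuted before fitting."""
    X_pos, X_neg = _class_matrices(session, config, classes)
    return resampled_decoding(X_pos, X_neg, config, classes, shuffle=True)


def single_unit_decoding(
    session: Session, config: ProtocolConfig
) -> tuple[dict[int, DecodingResult], int]:
    """Per-unit decoding on each unit's sub-vector; returns (results, best unit id)."""
    X_pos, X_neg = _class_matrices(session, config)
    n_units = session.n_units
    n_bins = X_pos.shape[1] // n_units
    results = {}
    for pos, uid in enumerate(session.unit_ids):
        cols = unit_columns(n_units, n_bins, pos)
        results[uid] = resampled_decoding(X_pos[:, cols], X_neg[:, cols], config)
    best = max(results, key=lambda uid: results[uid].mean_accuracy)
    return results, best


def bin_size_sweep(
    session: Session, sizes: Sequence[float], config: ProtocolConfig
) -> dict[float, DecodingResult]:
    """Full protocol at each bin size on the configured window."""
    out = {}
    for size in sizes:
        out[float(size)] = run_protocol(session, replace(config, bin_size=float(size)))
    return out


def single_bin_time_course(
    session: Session,
    config: ProtocolConfig,
    bin_size: float = 100.0,
    period: tuple[float, float] = (0.0, 2000.0),
) -> tuple[np.ndarray, list[DecodingResult]]:
    """Decoding from single time bins tiling the cue-on period.

    Returns bin start times (ms re cue) and one result per bin; each
    feature vector has dimension n_units (one count per unit).
    """
    start, end = period
    n_bins = int(round((end - start) / bin_size))
    trials_pos = select_trials(session, ["L-L"])
    trials_neg = select_trials(session, ["R-R"])

    def counts(trials, lo, hi):
        return np.array(
            [
                [tr.count(t.t_cue + lo, t.t_cue + hi) for tr in session.spike_trains]
                for t in trials
            ],
            dtype=float,
        )

    times = start + bin_size * np.arange(n_bins)
    results = []
    for j in range(n_bins):
        lo, hi = start + j * bin_size, start + (j + 1) * bin_size
        results.append(
            resampled_decoding(
                counts(trials_pos, lo, hi), counts(trials_neg, lo, hi), config
            )
        )
    return times, results


def ensemble_size_curve(
    session: Session,
    config: ProtocolConfig,
    sizes: Sequence[int],
    n_draws: int = 10,
) -> dict[int, float]:
    """Mean accuracy vs ensemble size over random unit subsets.

    For each size, ``n_draws`` subsets are drawn without replacement
    (all subsets when fewer exist) and their protocol accuracies
    averaged.
    """
    X_pos, X_neg = _class_matrices(session, config)
    n_units = session.n_units
    n_bins = X_pos.shape[1] // n_units
    out = {}
    for size in sizes:
        if size > n_units:
            raise ValueError(f"ensemble size {size} exceeds {n_units} units")
        all_subsets = list(combinations(range(n_units), size))
        rng = np.random.default_rng([config.seed, 977, size])
        if len(all_subsets) > n_draws:
            picks = [all_subsets[i] for i in rng.choice(len(all_subsets), n_draws, replace=False)]
        else:
            picks = all_subsets
        accs = []
        for subset in picks:
            cols = unit_columns(n_units, n_bins, list(subset))
            accs.append(
                resampled_decoding(X_pos[:, cols], X_neg[:, cols], config).mean_accuracy
            )
        out[int(size)] = float(np.mean(accs))
    return out


def error_trial_decoding(
    session: Session,
    pair: tuple[str, str],
    config: ProtocolConfig,
    min_trials: int = 20,
) -> DecodingResult | None:
    """Correct-vs-error decoding ('L-L' vs 'R-L', or 'R-R' vs 'L-R').

    Returns None when either class has fewer than ``min_trials`` trials
    (the session is ineligible for this analysis).
    """
    if set(pair) not in ({"L-L", "R-L"}, {"R-R", "L-R"}):
        raise ValueError(f"unsupported class pair {pair}")
    counts = session.class_counts()
    if any(counts[c] < min_trials for c in pair):
        return None
    return run_protocol(session, config, classes=pair)


def mean_rate_decoding(
    session: Session, config: ProtocolConfig
) -> DecodingResult:
    """Control decode from 1-D samples: the ensemble mean rate over the window.

    Each trial is reduced to a single number (total ensemble spike count
    in the window divided by n_units and window length), the lowest-
    resolution representation of the same data.
    """
    win = WINDOWS[config.window]
    length_s = (win.end - win.start) / 1000.0

    def scalars(cls):
        trials = select_trials(session, [cls])
        X = spike_count_matrix(session, trials, config.window, win.end - win.start)
        return X.sum(axis=1, keepdims=True) / (session.n_units * length_s)

    return resampled_decoding(scalars("L-L"), scalars("R-R"), config)
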