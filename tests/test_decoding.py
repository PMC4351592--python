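"""Spike-count vectorization, the linear decoder, and the resampled protocol."""

import numpy as np
import pytest

from choicedecode import (
    GeneratorConfig,
    ProtocolConfig,
    TrialAveragedLinearDecoder,
    bin_size_sweep,
    classify,
    ensemble_size_curve,
    error_trial_decoding,
    make_training_samples,
    mean_rate_decoding,
    run_protocol,
    shuffle_control,
    simulate_session,
    single_bin_time_course,
    single_unit_decoding,
    spike_count_matrix,
    spike_count_vector,
)
from choicedecode.task import select_trials, window_bounds
from conftest import make_trial


class TestSpikeCountVector:
    def test_dimension_three_bins_per_unit(self, tuned_session):
        t = tuned_session.trials[0]
        v = spike_count_vector(t, tuned_session.spike_trains, "CO", 500.0)
        assert v.shape == (3 * tuned_session.n_units,)

    def test_empty_trains_give_zero_vector(self):
        from choicedecode import SpikeTrain

        t = make_trial(t_cue=0.0)
        trains = [SpikeTrain(1, np.array([])), SpikeTrain(2, np.array([]))]
        v = spike_count_vector(t, trains, "CO", 500.0)
        assert v.shape == (6,) and not v.any()

    @pytest.mark.parametrize("bin_size", [100.0, 300.0, 500.0])
    def test_matches_brute_force_counting(self, tuned_session, bin_size):
        t = tuned_session.trials[3]
        v = spike_count_vector(t, tuned_session.spike_trains, "CO", bin_size)
        start, end = window_bounds("CO", t)
        n_bins = int(round((end - start) / bin_size))
        brute = []
        for train in sorted(tuned_session.spike_trains, key=lambda s: s.unit_id):
            ts = train.timestamps
            for j in range(n_bins):
                lo = start + j * bin_size
                brute.append(np.sum((ts >= lo) & (ts < lo + bin_size)))
        assert np.array_equal(v, np.array(brute, dtype=float))

    def test_non_divisor_bin_size_rejected_unless_truncation(self, tuned_session):
        t = tuned_session.trials[0]
        with pytest.raises(ValueError, match="does not divide"):
            spike_count_vector(t, tuned_session.spike_trains, "CO", 200.0)
        v = spike_count_vector(
            t, tuned_session.spike_trains, "CO", 200.0, allow_truncation=True
        )
        assert v.shape == (7 * tuned_session.n_units,)


class TestDecoder:
    def _fit_toy(self, **kw):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(2.0, 0.3, (20, 3)), rng.normal(-2.0, 0.3, (20, 3))])
        y = np.array(["L-L"] * 20 + ["R-R"] * 20)
        dec = TrialAveragedLinearDecoder(random_state=1, **kw)
        return dec.fit(X, y)

    def test_sign_rule_boundary_is_left(self):
        dec = self._fit_toy()
        dec.coef_ = np.array([1.0, 0.0, 0.0])
        dec.intercept_ = 0.0
        label, df = classify(dec, np.zeros(3))
        assert df == 0.0 and label == "L-L"
        label, df = classify(dec, np.array([-3.0, 0.0, 0.0]))
        assert df == -3.0 and label == "R-R"

    def test_dual_form_equals_expanded_linear_form(self, rng):
        """sum_i alpha_i (s_i . x) + b == w . x + b to 1e-9."""
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, "L-L", "R-R")
            if len(set(y)) < 2:
                continue
            dec = TrialAveragedLinearDecoder(n_average=1, random_state=0).fit(X, y)
            Xt = rng.normal(size=(10, 4))
            assert np.allclose(
                dec.dual_decision_function(Xt), dec.decision_function(Xt), atol=1e-9
            )

    def test_dimension_mismatch_rejected(self):
        dec = self._fit_toy()
        with pytest.raises(ValueError, match="dimension"):
            dec.decision_function(np.zeros(5))

    def test_lda_kind_fits_and_orients(self):
        dec = self._fit_toy(kind="lda")
        assert dec.predict(np.full((1, 3), 2.0))[0] == "L-L"
        assert dec.predict(np.full((1, 3), -2.0))[0] == "R-R"

    def test_sklearn_params_round_trip(self):
        dec = TrialAveragedLinearDecoder(C=2.0, n_average=3)
        assert dec.get_params()["C"] == 2.0
        dec.set_params(C=0.5)
        assert dec.C == 0.5


class TestTrainingSamples:
    def test_n_average_one_returns_raw_vectors(self, rng):
        raw = {"L-L": rng.normal(size=(6, 4)), "R-R": rng.normal(size=(5, 4))}
        X, y = make_training_samples(raw, 1, None, rng)
        assert np.array_equal(X[:6], raw["L-L"]) and np.array_equal(X[6:], raw["R-R"])

    def test_average_of_identical_vectors_is_idempotent(self, rng):
        v = np.arange(4.0)
        raw = {"L-L": np.tile(v, (5, 1)), "R-R": np.tile(-v, (5, 1))}
        X, y = make_training_samples(raw, 5, 3, rng)
        assert np.allclose(X[y == "L-L"], v)

    def test_known_vectors_hand_mean(self):
        raw = {"L-L": np.eye(5), "R-R": np.zeros((5, 5))}
        rng = np.random.default_rng(0)
        X, y = make_training_samples(raw, 5, 1, rng)
        # averaging all five distinct basis vectors gives the uniform vector
        assert np.allclose(X[y == "L-L"], 0.2)

    def test_too_few_raw_trials_names_the_class(self, rng):
        raw = {"L-L": np.zeros((3, 2)), "R-R": np.zeros((10, 2))}
        with pytest.raises(ValueError, match="L-L"):
            make_training_samples(raw, 5, None, rng)


class TestProtocol:
    def test_no_signal_accuracy_near_chance(self, flat_session):
        res = run_protocol(flat_session, ProtocolConfig(n_repeats=50, seed=6))
        assert 0.40 <= res.mean_accuracy <= 0.60

    def test_strong_signal_high_accuracy_positive_distance(self):
        cfg = GeneratorConfig(
            n_units=4, n_sessions=1, trials_per_class=50,
            tuning_amplitude_schedule=(8.0,), seed=41,
            behavior_accuracy=(0.8,), behavior_latency=(0.3,),
        )
        s = simulate_session(cfg, 1)
        res = run_protocol(s, ProtocolConfig(n_repeats=30, seed=7))
        assert res.mean_accuracy > 0.9
        assert res.class_distance > 0

    def test_fixed_seed_is_deterministic(self, tuned_session):
        cfg = ProtocolConfig(n_repeats=10, seed=8)
        a = run_protocol(tuned_session, cfg)
        b = run_protocol(tuned_session, cfg)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.class_distance == b.class_distance

    def test_infeasible_split_rejected(self, tuned_session):
        with pytest.raises(ValueError, match="averaging"):
            run_protocol(
                tuned_session,
                ProtocolConfig(n_repeats=2, trials_per_class=6, seed=0),
            )

    def test_shuffle_destroys_separable_signal(self, tuned_session):
        res = shuffle_control(tuned_session, ProtocolConfig(n_repeats=50, seed=9))
        assert 0.40 <= res.mean_accuracy <= 0.60

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for d in (0.0, 4.0, 8.0):
            cfg = GeneratorConfig(
                n_units=4, n_sessions=1, trials_per_class=50,
                tuning_amplitude_schedule=(d,), seed=51,
                behavior_accuracy=(0.8,), behavior_latency=(0.3,),
            )
            s = simulate_session(cfg, 1)
            accs.append(
                run_protocol(s, ProtocolConfig(n_repeats=30, seed=10)).mean_accuracy
            )
        assert accs[0] < accs[1] <= accs[2] + 0.03

    def test_lda_and_svm_agree_in_trend(self, tuned_session):
        svm = run_protocol(tuned_session, ProtocolConfig(n_repeats=30, seed=12))
        lda = run_protocol(
            tuned_session,
            ProtocolConfig(n_repeats=30, classifier_kind="lda", seed=12),
        )
        assert svm.mean_accuracy > 0.6 and lda.mean_accuracy > 0.6


class TestSingleUnitAndSubsets:
    def test_one_unit_ensemble_equals_single_unit(self):
        cfg = GeneratorConfig(
            n_units=1, n_sessions=1, trials_per_class=40,
            tuning_amplitude_schedule=(4.0,), seed=61,
            behavior_accuracy=(0.8,), behavior_latency=(0.3,),
        )
        s = simulate_session(cfg, 1)
        pc = ProtocolConfig(n_repeats=15, seed=13)
        per_unit, best = single_unit_decoding(s, pc)
        full = run_protocol(s, pc)
        assert best == 1
        assert per_unit[1].mean_accuracy == pytest.approx(full.mean_accuracy)

    def test_subvector_extraction_matches_brute_force(self, tuned_session):
        trials = select_trials(tuned_session, ["L-L"])[:5]
        X = spike_count_matrix(tuned_session, trials, "CO", 500.0)
        # unit at position 2 occupies columns 6..8 in unit-major layout
        sub = X[:, 6:9]
        brute = np.array(
            [
                spike_count_vector(
                    t, [tuned_session.spike_trains[2]], "CO", 500.0
                )
                for t in trials
            ]
        )
        assert np.array_equal(sub, brute)

    def test_ensemble_at_least_matches_best_single_unit(self, tuned_session):
        pc = ProtocolConfig(n_repeats=20, seed=14)
        per_unit, best = single_unit_decoding(tuned_session, pc)
        full = run_protocol(tuned_session, pc)
        assert full.mean_accuracy >= per_unit[best].mean_accuracy - 0.05

    def test_ensemble_size_curve(self, tuned_session):
        pc = ProtocolConfig(n_repeats=10, seed=15)
        curve = ensemble_size_curve(tuned_session, pc, sizes=[1, 2, 4], n_draws=3)
        full = run_protocol(tuned_session, pc)
        assert curve[4] == pytest.approx(full.mean_accuracy)
        assert curve[1] <= curve[4] + 0.03
        with pytest.raises(ValueError, match="exceeds"):
            ensemble_size_curve(tuned_session, pc, sizes=[9])


class TestBinSizeAndTimeCourse:
    def test_non_divisor_size_rejected(self, tuned_session):
        with pytest.raises(ValueError, match="does not divide"):
            bin_size_sweep(tuned_session, [200.0], ProtocolConfig(n_repeats=5, seed=0))

    def test_pattern_signal_needs_temporal_resolution(self):
        """pattern_rotation separates at 500 ms bins but not in a single bin."""
        cfg = GeneratorConfig(
            n_units=4, n_sessions=1, trials_per_class=56,
            pattern_mode="pattern_rotation", tuning_amplitude_schedule=(6.0,),
            seed=71, behavior_accuracy=(0.8,), behavior_latency=(0.3,),
        )
        s = simulate_session(cfg, 1)
        pc = ProtocolConfig(n_repeats=30, seed=16)
        sweep = bin_size_sweep(s, [500.0, 1500.0], pc)
        assert sweep[500.0].mean_accuracy > sweep[1500.0].mean_accuracy + 0.1
        # the 1-D ensemble mean rate carries no class information either
        assert mean_rate_decoding(s, pc).mean_accuracy < 0.6

    def test_single_bin_time_course_follows_onset(self, tuned_session):
        pc = ProtocolConfig(n_repeats=15, seed=17)
        times, results = single_bin_time_course(tuned_session, pc, bin_size=500.0)
        accs = np.array([r.mean_accuracy for r in results])
        assert times.size == 4
        pre = accs[0]  # [0, 500): mostly before the 400 ms onset
        post = accs[2:]  # [1000, 2000): fully modulated
        assert pre < 0.65
        assert post.min() > 0.6
        # multi-bin decoding at least matches the best single bin
        full = run_protocol(tuned_session, pc)
        assert full.mean_accuracy >= accs.max() - 0.05


class TestErrorTrialDecoding:
    def _session(self, error_tuning, acc=0.5, seed=81):
        cfg = GeneratorConfig(
            n_units=4, n_sessions=1, trials_per_class=40,
            tuning_amplitude_schedule=(6.0,), error_tuning=error_tuning,
            behavior_accuracy=(acc,), behavior_latency=(0.3,), seed=seed,
        )
        return simulate_session(cfg, 1)

    def test_too_few_error_trials_ineligible(self):
        s = self._session("choice", acc=0.95)  # few error trials
        assert s.class_counts()["R-L"] < 20
        res = error_trial_decoding(s, ("L-L", "R-L"), ProtocolConfig(n_repeats=5, seed=0))
        assert res is None

    def test_choice_tuned_errors_look_like_correct_trials(self):
        s = self._session("choice")
        res = error_trial_decoding(s, ("L-L", "R-L"), ProtocolConfig(n_repeats=30, seed=18))
        assert res is not None
        assert 0.35 <= res.mean_accuracy <= 0.65

    def test_cue_tuned_errors_are_separable(self):
        s = self._session("cue")
        res = error_trial_decoding(s, ("R-R", "L-R"), ProtocolConfig(n_repeats=30, seed=19))
        assert res is not None
        assert res.mean_accuracy > 0.7

    def test_unsupported_pair_rejected(self, tuned_session):
        with pytest.raises(ValueError, match="pair"):
            error_trial_decoding(
                tuned_session, ("L-L", "R-R"), ProtocolConfig(n_repeats=5, seed=0)
            )
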