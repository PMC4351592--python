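import numpy as np
import pytest

from choicedecode import GeneratorConfig, ProtocolConfig, simulate_session


def make_trial(t_cue=0.0, cue="L", press="left", latency_ms=300.0, outcome=None):
    from choicedecode.task import Trial, cue_direction

    if outcome is None:
        outcome = "success" if cue_direction(cue) == press else "failure"
    t_press = t_cue + 2000.0 + latency_ms
    return Trial(
        cue_side=cue,
        first_press_side=press,
        t_ready=t_cue,
        t_cue=t_cue,
        t_extend=t_cue + 2000.0,
        t_press=t_press,
        t_feedback=t_press + 1000.0,
        outcome=outcome,
    )


@pytest.fixture(scope="session")
def tuned_session():
    """4 units, 50 trials/class, 4 Hz class separation (rate offset)."""
    cfg = GeneratorConfig(
        n_units=4,
        n_sessions=2,
        trials_per_class=50,
        tuning_amplitude_schedule=(4.0, 4.0),
        seed=11,
    )
    return simulate_session(cfg, 1)


@pytest.fixture(scope="session")
def flat_session():
    """No class separation: d = 0."""
    cfg = GeneratorConfig(
        n_units=4,
        n_sessions=2,
        trials_per_class=50,
        tuning_amplitude_schedule=(0.0, 0.0),
        seed=12,
    )
    return simulate_session(cfg, 1)


@pytest.fixture()
def fast_protocol():
    return ProtocolConfig(n_repeats=20, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
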