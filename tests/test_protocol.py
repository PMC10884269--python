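"""Scheduling, scoring, session timing and the feedback bootstrap."""

from collections import Counter

import numpy as np
import pytest

from sispin.corpus import COLOURS, NUMBERS, SentenceSpec
from sispin.protocol import (
    EXPERIMENTAL_CONDITIONS,
    InterfaceTimingModel,
    SessionAborted,
    Trial,
    data_collection_duration,
    feedback_overhead_bootstrap,
    make_schedule,
    make_training,
    nominal_stimulus_duration,
    run_session,
    score_response,
)
from sispin.listener import PsychometricParams, SimulatedListener


def test_design_has_twelve_experimental_conditions():
    assert len(EXPERIMENTAL_CONDITIONS) == 12
    labels = {c.label for c in EXPERIMENTAL_CONDITIONS}
    assert len(labels) == 12


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_schedule_multiset_invariant(seed):
    """91 trials: every condition (incl. baseline) appears exactly 7 times."""
    trials = make_schedule(seed)
    assert len(trials) == 91
    counts = Counter(t.condition.label for t in trials)
    assert len(counts) == 13
    assert set(counts.values()) == {7}
    assert all(t.target.call_sign == "dog" for t in trials)


def test_schedules_differ_across_seeds():
    a = [t.condition.label for t in make_schedule(1)]
    b = [t.condition.label for t in make_schedule(2)]
    assert a != b
    assert Counter(a) == Counter(b)


def test_first_trial_condition_roughly_uniform():
    """First-trial condition frequencies are consistent with a uniform draw."""
    from scipy import stats

    firsts = Counter(make_schedule(s)[0].condition.label for s in range(2000))
    observed = np.array([firsts.get(c, 0) for c in sorted(firsts)])
    chi2, p = stats.chisquare(observed)
    assert p > 0.001


def test_training_phase_structure():
    for seed in range(5):
        training = make_training(seed)
        assert len(training) == 4
        assert [t.condition.tmr_db for t in training] == [0.0, 0.0, 6.0, 6.0]
        assert all(t.is_training for t in training)
        assert all(t.condition.voice.startswith("train") for t in training)


def test_scoring_requires_both_keywords():
    assert score_response(("pink", "5"), ("pink", "5"))
    assert not score_response(("pink", "5"), ("pink", "4"))
    assert not score_response(("pink", "5"), ("red", "5"))
    with pytest.raises(ValueError, match="matrix"):
        score_response(("pink", "5"), ("orange", "5"))


def test_scoring_symmetric_under_relabeling(rng):
    """Permuting colour and number labels never changes correctness."""
    perm_c = dict(zip(COLOURS, rng.permutation(COLOURS)))
    perm_n = dict(zip(NUMBERS, rng.permutation(NUMBERS)))
    for _ in range(100):
        t = (COLOURS[rng.integers(6)], NUMBERS[rng.integers(8)])
        r = (COLOURS[rng.integers(6)], NUMBERS[rng.integers(8)])
        assert score_response(t, r) == score_response(
            (perm_c[t[0]], perm_n[t[1]]), (perm_c[r[0]], perm_n[r[1]])
        )


class _FixedListener:
    """Always answers with a fixed (possibly correct) response, zero latency."""

    def __init__(self, correct=True, latency=0.0):
        self.correct = correct
        self.latency = latency

    def respond(self, trial, rng):
        if self.correct:
            return trial.target.colour, trial.target.number, self.latency
        wrong = "red" if trial.target.colour != "red" else "green"
        return wrong, trial.target.number, self.latency


def test_robot_feedback_total_all_correct():
    """All-correct robot session: feedback totals 91 nods of 2.5 s."""
    session = run_session(_FixedListener(True), "robot", rng_seed=1)
    assert len(session.trials) == 91
    assert sum(t.feedback_time for t in session.trials) == pytest.approx(91 * 2.5)


def test_computer_feedback_zero_when_correct():
    session = run_session(_FixedListener(True), "computer", rng_seed=1)
    assert sum(t.feedback_time for t in session.trials) == 0.0


def test_session_determinism():
    params = PsychometricParams()
    a = run_session(SimulatedListener(params, "robot"), "robot", rng_seed=7)
    b = run_session(SimulatedListener(params, "robot"), "robot", rng_seed=7)
    assert a.trials == b.trials


def test_duration_matches_hand_computation():
    """Duration = stimulus + latency per trial + feedback and breaks between."""
    timing = InterfaceTimingModel()
    session = run_session(_FixedListener(True, latency=2.0), "robot",
                          timing=timing, rng_seed=3)
    stim_total = sum(
        nominal_stimulus_duration(
            Trial(t.index, t.condition, SentenceSpec("dog", *t.target))
        )
        for t in session.trials
    )
    expected = (
        stim_total
        + 2.0 * 91          # listener latency
        + 2.5 * 90          # nods between trials (last one not counted)
        + 10.0 * 2          # two robot break waits
    )
    assert data_collection_duration(session) * 60 == pytest.approx(expected)


def test_robot_slower_than_computer_by_feedback_delta():
    timing = InterfaceTimingModel()
    robot = run_session(_FixedListener(False), "robot", timing=timing, rng_seed=5)
    comp = run_session(_FixedListener(False), "computer", timing=timing, rng_seed=5)
    delta = (
        data_collection_duration(robot) - data_collection_duration(comp)
    ) * 60
    # all-incorrect: 90 inter-trial feedbacks differ by (3.2 - 0.5) s,
    # plus two 10 s robot break waits
    assert delta == pytest.approx(90 * (3.2 - 0.5) + 20.0)


def test_single_trial_session_duration():
    schedule = make_schedule(0)[:1]
    session = run_session(_FixedListener(True, latency=1.5), "computer",
                          rng_seed=0, schedule=schedule)
    expected = nominal_stimulus_duration(schedule[0]) + 1.5
    assert data_collection_duration(session) * 60 == pytest.approx(expected)


def test_listener_failure_aborts_with_partial_log():
    class Flaky:
        def __init__(self):
            self.n = 0

        def respond(self, trial, rng):
            self.n += 1
            if self.n > 10:
                raise RuntimeError("lost attention")
            return trial.target.colour, trial.target.number, 0.0

    with pytest.raises(SessionAborted) as err:
        run_session(Flaky(), "computer", rng_seed=0)
    assert err.value.partial.aborted
    assert len(err.value.partial.trials) == 6  # 4 training trials consumed first


def test_bootstrap_degenerate_probabilities():
    mean1, sd1 = feedback_overhead_bootstrap(1.0, n_boot=1000, rng_seed=0)
    assert mean1 * 60 == pytest.approx(91 * 2.5)
    assert sd1 == pytest.approx(0.0, abs=1e-9)
    mean0, sd0 = feedback_overhead_bootstrap(0.0, n_boot=1000, rng_seed=0)
    assert mean0 * 60 == pytest.approx(91 * 3.2)
    assert sd0 == pytest.approx(0.0, abs=1e-9)


def test_bootstrap_matches_binomial_closed_form():
    p = 0.8
    mean, sd = feedback_overhead_bootstrap(p, n_boot=20000, rng_seed=1)
    expected_s = 91 * (2.5 * p + 3.2 * (1 - p))
    sd_theory = abs(3.2 - 2.5) * np.sqrt(91 * p * (1 - p))
    assert mean * 60 == pytest.approx(expected_s, abs=3 * sd_theory / np.sqrt(20000))
    assert sd == pytest.approx(sd_theory, rel=0.05)


def test_bootstrap_rejects_bad_probability():
    with pytest.raises(ValueError):
        feedback_overhead_bootstrap(1.2)
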