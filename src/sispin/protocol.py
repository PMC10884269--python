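"""Trial scheduling, scoring, session execution and interface timing.

A data-collection block is a seeded random permutation of 91 trials: the 12
experimental conditions (3 TMRs x 4 masker voice conditions) with 7 trials
each, plus 7 no-masker baseline trials.  Training is 4 trials drawn from a
3 x 3 grid of voice offsets and is never scored.  A response is correct
only when both the colour and the number match the target.

The interface timing model captures what differs between the two setups:
the robot gives embodied feedback after every response (a 2.5 s head nod
when correct, a 3.2 s head shake when not), while the computer shows only a
brief negative-feedback outline; break handling differs likewise.  Listener
latency belongs to the listener model, not to the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np

from .corpus import COLOURS, NUMBERS, SentenceSpec, TOKEN_GAP_S, keyword_token
from .masker import MaskerBuildParams, TMR_SET_DB
from .voice import TRAINING_GRID, VOICE_CONDITIONS, VoiceCondition

__all__ = [
    "Condition",
    "EXPERIMENTAL_CONDITIONS",
    "BASELINE_CONDITION",
    "Trial",
    "TrialResult",
    "SessionResult",
    "InterfaceTimingModel",
    "SessionAborted",
    "make_schedule",
    "make_training",
    "score_response",
    "nominal_stimulus_duration",
    "run_session",
    "feedback_overhead_bootstrap",
    "data_collection_duration",
    "TRIALS_PER_CONDITION",
    "N_DATA_TRIALS",
]

TRIALS_PER_CONDITION = 7
N_TRAINING_TRIALS = 4


@dataclass(frozen=True)
class Condition:
    """One cell of the design: a TMR x voice-condition pair, or baseline."""

    tmr_db: float | None
    voice: str | None
    baseline: bool = False

    @property
    def label(self) -> str:
        if self.baseline:
            return "baseline"
        return f"tmr{self.tmr_db:+g}_{self.voice}"


EXPERIMENTAL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(tmr, vc.name) for tmr in TMR_SET_DB for vc in VOICE_CONDITIONS
)
BASELINE_CONDITION = Condition(None, None, baseline=True)
N_DATA_TRIALS = TRIALS_PER_CONDITION * (len(EXPERIMENTAL_CONDITIONS) + 1)  # 91


@dataclass(frozen=True)
class Trial:
    index: int
    condition: Condition
    target: SentenceSpec
    is_training: bool = False


@dataclass(frozen=True)
class TrialResult:
    index: int
    condition: Condition
    target: tuple[str, str]
    response: tuple[str, str]
    correct: bool
    present_time: float
    response_time: float
    feedback_time: float


@dataclass
class SessionResult:
    participant_id: str
    interface: str
    trials: list[TrialResult] = field(default_factory=list)
    aborted: bool = False

    @property
    def data_collection_duration_min(self) -> float:
        return data_collection_duration(self)


@dataclass(frozen=True)
class InterfaceTimingModel:
    """Per-interface feedback and break timings, in seconds."""

    nod_s: float = 2.5
    shake_s: float = 3.2
    computer_negative_s: float = 0.5
    break_wait_s: float = 10.0
    break_points: tuple[int, ...] = (30, 60)
    computer_break_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nod_s", "shake_s", "computer_negative_s", "break_wait_s",
                     "computer_break_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def feedback_s(self, interface: str, correct: bool) -> float:
        if interface == "robot":
            return self.nod_s if correct else self.shake_s
        if interface == "computer":
            return 0.0 if correct else self.computer_negative_s
        raise ValueError(f"unknown interface {interface!r}")

    def break_s(self, interface: str) -> float:
        return self.break_wait_s if interface == "robot" else self.computer_break_s


class Listener(Protocol):
    def respond(
        self, trial: Trial, rng: np.random.Generator
    ) -> tuple[str, str, float]:  # (colour, number, latency_s)
        ...


class SessionAborted(RuntimeError):
    """Raised when the listener fails mid-session; carries the partial log."""

    def __init__(self, message: str, partial: SessionResult):
        super().__init__(message)
        self.partial = partial


def _target_pool() -> list[SentenceSpec]:
    return [SentenceSpec("dog", c, n) for c in COLOURS for n in NUMBERS]


def make_schedule(rng_seed: int | np.random.Generator) -> list[Trial]:
    """Seeded random order of the 91-trial data-collection block.

    Every experimental condition appears exactly 7 times, the baseline 7
    times; each trial's target sentence is drawn uniformly from the
    48-sentence "dog" corpus.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pool = _target_pool()
    conditions: list[Condition] = []
    for cond in (*EXPERIMENTAL_CONDITIONS, BASELINE_CONDITION):
        conditions.extend([cond] * TRIALS_PER_CONDITION)
    order = rng.permutation(len(conditions))
    trials = []
    for i, j in enumerate(order):
        target = pool[int(rng.integers(len(pool)))]
        trials.append(Trial(index=i, condition=conditions[int(j)], target=target))
    return trials


def make_training(rng_seed: int | np.random.Generator) -> list[Trial]:
    """Four unscored training trials from the 9-combination voice grid.

    The first two trials run at 0 dB TMR, the remaining ones at +6 dB.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pool = _target_pool()
    picks = rng.choice(len(TRAINING_GRID), size=N_TRAINING_TRIALS, replace=False)
    trials = []
    for i, k in enumerate(picks):
        vc: VoiceCondition = TRAINING_GRID[int(k)]
        tmr = 0.0 if i < 2 else 6.0
        target = pool[int(rng.integers(len(pool)))]
        trials.append(
            Trial(
                index=i,
                condition=Condition(tmr, vc.name),
                target=target,
                is_training=True,
            )
        )
    return trials


def score_response(
    target: tuple[str, str] | SentenceSpec, response: tuple[str, str]
) -> bool:
    """Correct iff both the colour and the number match the target."""
    if isinstance(target, SentenceSpec):
        target = (target.colour, target.number)
    t_colour, t_number = target
    r_colour, r_number = response
    if r_colour not in COLOURS or r_number not in NUMBERS:
        raise ValueError(
            f"response {response!r} outside the {len(COLOURS)}x{len(NUMBERS)} matrix"
        )
    return r_colour == t_colour and r_number == t_number


def nominal_stimulus_duration(
    trial: Trial, params: MaskerBuildParams = MaskerBuildParams()
) -> float:
    """Stimulus play time for a trial, from token metadata (no rendering).

    Masked trials add the masker lead and tail around the target sentence.
    """
    tokens = trial.target.tokens()
    dur = sum(t.nominal_duration for t in tokens) + TOKEN_GAP_S * (len(tokens) - 1)
    if not trial.condition.baseline:
        dur += params.lead + params.tail
    return dur


def run_session(
    listener: Listener,
    interface: str,
    timing: InterfaceTimingModel = InterfaceTimingModel(),
    rng_seed: int | np.random.Generator = 0,
    participant_id: str = "p00",
    schedule: Sequence[Trial] | None = None,
    stimulus_duration: Callable[[Trial], float] | None = None,
) -> SessionResult:
    """Run training plus the 91-trial data block on one interface.

    The simulation clock accumulates, per trial, the stimulus duration, the
    listener's response latency, the interface feedback time, and any break
    time at the configured break points.  Only data trials are logged.
    Deterministic for a fixed seed.
    """
    if interface not in ("computer", "robot"):
        raise ValueError(f"interface must be 'computer' or 'robot', got {interface!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    stimulus_duration = stimulus_duration or nominal_stimulus_duration
    training = make_training(rng)
    data_trials = list(schedule) if schedule is not None else make_schedule(rng)
    session = SessionResult(participant_id=participant_id, interface=interface)
    clock = 0.0
    # training phase: executed for listener state/realism, never logged
    for trial in training:
        try:
            _c, _n, latency = listener.respond(trial, rng)
        except Exception as exc:  # noqa: BLE001 - listener contract violation
            session.aborted = True
            raise SessionAborted(f"listener failed on training trial: {exc}", session)
        correct = score_response(trial.target, (_c, _n))
        clock += stimulus_duration(trial) + max(0.0, latency)
        clock += timing.feedback_s(interface, correct)
    clock = 0.0  # data-collection duration is measured from the first data trial
    for n_done, trial in enumerate(data_trials, start=1):
        present = clock
        try:
            colour, number, latency = listener.respond(trial, rng)
        except Exception as exc:  # noqa: BLE001
            session.aborted = True
            raise SessionAborted(
                f"listener failed on trial {trial.index}: {exc}", session
            )
        correct = score_response(trial.target, (colour, number))
        response_time = present + stimulus_duration(trial) + max(0.0, latency)
        fb = timing.feedback_s(interface, correct)
        session.trials.append(
            TrialResult(
                index=trial.index,
                condition=trial.condition,
                target=(trial.target.colour, trial.target.number),
                response=(colour, number),
                correct=correct,
                present_time=present,
                response_time=response_time,
                feedback_time=fb,
            )
        )
        clock = response_time + fb
        if n_done in timing.break_points:
            clock += timing.break_s(interface)
    return session


def data_collection_duration(session: SessionResult) -> float:
    """Block duration in minutes: first presentation to last logged response.

    Breaks inside the block count; training and pre/post interaction do not
    (they are never part of the trial log), nor does feedback after the
    final response.
    """
    if not session.trials:
        raise ValueError("session has no logged trials")
    first = session.trials[0].present_time
    last = session.trials[-1].response_time
    return (last - first) / 60.0


def feedback_overhead_bootstrap(
    p_correct: float,
    n_trials: int = N_DATA_TRIALS,
    timing: InterfaceTimingModel = InterfaceTimingModel(),
    n_boot: int = 10000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap the total robot head-movement time added over a block.

    Each replicate draws ``n_trials`` Bernoulli(p_correct) outcomes and sums
    the nod/shake durations.  Returns (mean in minutes, sd in seconds).
    """
    if not (0.0 <= p_correct <= 1.0):
        raise ValueError(f"p_correct must be in [0, 1], got {p_correct}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_correct = rng.binomial(n_trials, p_correct, size=n_boot)
    totals = n_correct * timing.nod_s + (n_trials - n_correct) * timing.shake_s
    return float(np.mean(totals) / 60.0), float(np.std(totals))
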