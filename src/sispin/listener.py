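"""Simulated listeners, questionnaire and behaviour-count generators.

This module is the synthetic-data side of the pipeline: it replaces human
participants with a psychometric response model, produces Likert
questionnaire data with the NARS subscale structure, and produces
two-coder behaviour-count tables with controllable inter-coder noise.

The listener model composes a guessing floor (1/48 for the 6 x 8 response
matrix), a lapse rate, and a logistic core driven by the TMR in dB and
indicator benefits for an F0 difference, a VTL difference, their
combination, and the interface.  Defaults are chosen to reproduce the
qualitative psychometric pattern of speech-on-speech listening: near-ceiling
accuracy at +6 dB TMR for every voice condition, and strongly degraded
accuracy at -6 dB when target and masker share the same voice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import COLOURS, NUMBERS
from .protocol import (
    InterfaceTimingModel,
    SessionResult,
    Trial,
    make_schedule,
    run_session,
)
from .voice import VOICE_CONDITIONS

__all__ = [
    "PsychometricParams",
    "CohortSpec",
    "SimulatedListener",
    "p_correct",
    "generate_cohort",
    "NARS_ITEMS",
    "NARS_SUBSCALE_SIZES",
    "NARS_NEUTRAL_TOTALS",
    "nars_attainable_range",
    "generate_nars",
    "BEHAVIOURS",
    "CodingRecord",
    "generate_coding",
]

_GUESS_RATE = 1.0 / (len(COLOURS) * len(NUMBERS))  # 1/48

_VOICE_DELTAS = {vc.name: (vc.delta_f0, vc.delta_vtl) for vc in VOICE_CONDITIONS}


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the simulated listener's accuracy and latency model."""

    intercept: float = 1.2
    slope_per_db: float = 0.55
    benefit_f0: float = 1.5
    benefit_vtl: float = 1.0
    benefit_interaction: float = 0.5
    lapse_rate: float = 0.02
    guess_rate: float = _GUESS_RATE
    interface_effect: float = 0.0
    latency_mean_s: float = 3.5
    latency_sd_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must be in [0, 1)")
        if not (0.0 <= self.guess_rate < 1.0):
            raise ValueError("guess_rate must be in [0, 1)")


def p_correct(
    params: PsychometricParams,
    tmr_db: float | None,
    delta_f0: float = 0.0,
    delta_vtl: float = 0.0,
    interface: str = "computer",
    baseline: bool = False,
) -> float:
    """Probability of reporting both keywords correctly for one condition.

    Baseline (no masker) trials bypass the logistic core and return
    ``1 - lapse_rate``.  Voice benefits are indicator terms: they apply
    whenever the corresponding cue differs from the target at all, matching
    the 4-level condition factor of the design.
    """
    if baseline or tmr_db is None:
        return 1.0 - params.lapse_rate
    x = params.intercept + params.slope_per_db * float(tmr_db)
    has_f0 = delta_f0 != 0.0
    has_vtl = delta_vtl != 0.0
    if has_f0:
        x += params.benefit_f0
    if has_vtl:
        x += params.benefit_vtl
    if has_f0 and has_vtl:
        x += params.benefit_interaction
    if interface == "robot":
        x += params.interface_effect
    span = 1.0 - params.guess_rate - params.lapse_rate
    return float(params.guess_rate + span * _logistic(x))


class SimulatedListener:
    """A listener that answers trials according to a psychometric model.

    With probability ``p_correct`` the target pair is returned; otherwise a
    uniform draw from the other 47 matrix cells.  Latency is Normal,
    truncated at zero.
    """

    def __init__(self, params: PsychometricParams = PsychometricParams(),
                 interface: str = "computer"):
        self.params = params
        self.interface = interface

    def _trial_p(self, trial: Trial) -> float:
        cond = trial.condition
        if cond.baseline:
            return p_correct(self.params, None, baseline=True)
        df0, dvtl = _VOICE_DELTAS[cond.voice] if cond.voice in _VOICE_DELTAS else (
            0.0, 0.0
        )
        if cond.voice and cond.voice.startswith("train"):
            # training grid names encode their offsets
            parts = cond.voice.removeprefix("train_f0").split("_vtl")
            df0, dvtl = float(parts[0]), float(parts[1])
        return p_correct(self.params, cond.tmr_db, df0, dvtl, self.interface)

    def respond(
        self, trial: Trial, rng: np.random.Generator
    ) -> tuple[str, str, float]:
        p = self._trial_p(trial)
        target = (trial.target.colour, trial.target.number)
        if rng.random() < p:
            colour, number = target
        else:
            cells = [
                (c, n) for c in COLOURS for n in NUMBERS if (c, n) != target
            ]
            colour, number = cells[int(rng.integers(len(cells)))]
        latency = max(0.0, rng.normal(self.params.latency_mean_s,
                                      self.params.latency_sd_s))
        return colour, number, latency


@dataclass(frozen=True)
class CohortSpec:
    """Population description for a simulated participant cohort."""

    n_participants: int = 27
    between_subject_sd: float = 0.35  # sd of the per-participant intercept shift
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


def generate_cohort(
    cohort: CohortSpec = CohortSpec(),
    params: PsychometricParams = PsychometricParams(),
    timing: InterfaceTimingModel = InterfaceTimingModel(),
) -> list[tuple[SessionResult, SessionResult]]:
    """Paired (computer, robot) sessions for every simulated participant.

    Each participant gets an intercept drawn around the population value and
    keeps it for both sessions (the repeated-measures structure); interface
    order is counterbalanced by seed.  Stimulus randomisation (schedule and
    targets) is re-drawn per participant and per interface, mirroring the
    per-participant splicing randomisation of the protocol.
    """
    root = np.random.default_rng(cohort.rng_seed)
    pairs = []
    for i in range(cohort.n_participants):
        shift = root.normal(0.0, cohort.between_subject_sd)
        p_params = replace(params, intercept=params.intercept + shift)
        order = ("computer", "robot") if i % 2 == 0 else ("robot", "computer")
        sessions = {}
        for interface in order:
            listener = SimulatedListener(p_params, interface)
            seed = int(root.integers(2**31 - 1))
            sessions[interface] = run_session(
                listener,
                interface,
                timing,
                rng_seed=seed,
                participant_id=f"p{i:02d}",
            )
        pairs.append((sessions["computer"], sessions["robot"]))
    return pairs


# --- NARS questionnaires -----------------------------------------------------

#: (subscale, reverse-coded) per item, in presentation order: 6 items in S1,
#: 5 in S2, 3 in S3; the three S3 items are the reverse-coded ones.
NARS_ITEMS: tuple[tuple[str, bool], ...] = (
    *[("S1", False)] * 6,
    *[("S2", False)] * 5,
    *[("S3", True)] * 3,
)
NARS_SUBSCALE_SIZES = {"S1": 6, "S2": 5, "S3": 3}
#: Subscale totals when every item is answered "neutral" (3).
NARS_NEUTRAL_TOTALS = {"S1": 18, "S2": 15, "S3": 9}
#: Default generator targets (population subscale means).
NARS_DEFAULT_TARGETS = {"S1": 14.8, "S2": 15.8, "S3": 8.5}


def nars_attainable_range(subscale: str) -> tuple[int, int]:
    k = NARS_SUBSCALE_SIZES[subscale]
    return k, 5 * k


def generate_nars(
    n: int,
    subscale_targets: dict[str, float] | None = None,
    sd: float = 2.0,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Raw 1-5 Likert responses, shape (n, 14), in presentation order.

    Item responses are generated so that the expected subscale totals
    (computed with reverse-coded items contributing ``6 - rating``) match
    ``subscale_targets``; reverse items are stored raw, exactly as a
    respondent would tick them.
    """
    if n < 1:
        raise ValueError("need at least one respondent")
    targets = dict(NARS_DEFAULT_TARGETS, **(subscale_targets or {}))
    for sub, t in targets.items():
        lo, hi = nars_attainable_range(sub)
        if not (lo <= t <= hi):
            raise ValueError(
                f"target {t} for {sub} outside attainable range [{lo}, {hi}]"
            )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.empty((n, len(NARS_ITEMS)), dtype=int)
    for r in range(n):
        for sub in NARS_SUBSCALE_SIZES:
            k = NARS_SUBSCALE_SIZES[sub]
            lo, hi = nars_attainable_range(sub)
            total = int(np.clip(round(rng.normal(targets[sub], sd)), lo, hi))
            # distribute the total over k items, each in 1..5
            contribs = np.full(k, total // k)
            for j in range(total - int(contribs.sum())):
                contribs[j % k] += 1
            # random redistribution that keeps the sum and the 1..5 bounds
            for _ in range(2 * k):
                i, j = rng.integers(k), rng.integers(k)
                if i != j and contribs[i] < 5 and contribs[j] > 1:
                    contribs[i] += 1
                    contribs[j] -= 1
            idx = [m for m, (s, _) in enumerate(NARS_ITEMS) if s == sub]
            for pos, c in zip(idx, contribs):
                reverse = NARS_ITEMS[pos][1]
                out[r, pos] = int(6 - c) if reverse else int(c)
    return out


# --- two-coder behaviour counts ---------------------------------------------

BEHAVIOURS = ("smiling", "laughing", "frowning", "grimacing")


@dataclass(frozen=True)
class CodingRecord:
    coder_id: str
    segment_id: str
    interface: str
    counts: dict[str, int] = field(hash=False)


#: Mean counts per video segment; robot segments show more smiling (the
#: qualitative engagement pattern the generator emulates).
DEFAULT_RATES = {
    "computer": {"smiling": 1.0, "laughing": 0.3, "frowning": 1.5, "grimacing": 0.4},
    "robot": {"smiling": 3.0, "laughing": 0.5, "frowning": 0.8, "grimacing": 0.4},
}


def generate_coding(
    n_participants: int = 27,
    rates: dict[str, dict[str, float]] | None = None,
    coder_noise: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> list[CodingRecord]:
    """Behaviour counts logged by two coders over per-participant segments.

    A latent Poisson count per (participant, interface, behaviour) is shared
    by both coders; each coder then perturbs it with rounded Normal noise of
    sd ``coder_noise`` (clipped at zero), so ``coder_noise=0`` yields
    perfectly agreeing coders.
    """
    rates = rates or DEFAULT_RATES
    for iface, by_b in rates.items():
        for b, r in by_b.items():
            if r < 0:
                raise ValueError(f"negative rate for {iface}/{b}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    records = []
    for i in range(n_participants):
        for interface, by_behaviour in rates.items():
            latent = {
                b: int(rng.poisson(rate)) for b, rate in by_behaviour.items()
            }
            for coder in ("C01", "C02"):
                counts = {}
                for b, base in latent.items():
                    noise = rng.normal(0.0, coder_noise) if coder_noise > 0 else 0.0
                    counts[b] = max(0, int(round(base + noise)))
                records.append(
                    CodingRecord(
                        coder_id=coder,
                        segment_id=f"p{i:02d}_{interface}",
                        interface=interface,
                        counts=counts,
                    )
                )
    return records
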