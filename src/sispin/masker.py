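"""Spliced speech maskers and target+masker mixing at controlled TMRs.

The masker for a trial is built by repeatedly drawing random 150-300 ms
segments from eligible masker-corpus sentences (sentences sharing neither
the colour nor the number keyword with the target), shaping each segment
with 50 ms raised-cosine on/off ramps, and butt-joint concatenating until
the masker covers the target plus a 750 ms lead and a 250 ms tail.  The
masker gain is then set so that the broadband RMS ratio between the target
track and the masker track equals the requested target-to-masker ratio
(TMR) in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acoustics import rms
from .corpus import RenderedSentence, SentenceSpec

__all__ = [
    "MaskerBuildParams",
    "Stimulus",
    "TMR_SET_DB",
    "select_masker_sentences",
    "splice_masker",
    "mix_at_tmr",
    "baseline_stimulus",
    "make_stimulus",
]

#: The three TMR levels of the experimental design, in dB.
TMR_SET_DB = (-6.0, 0.0, 6.0)


@dataclass(frozen=True)
class MaskerBuildParams:
    """Timing constants of the masker construction."""

    segment_min: float = 0.150
    segment_max: float = 0.300
    ramp: float = 0.050
    lead: float = 0.750
    tail: float = 0.250

    def __post_init__(self) -> None:
        if self.segment_min < 2 * self.ramp:
            raise ValueError("segment_min must be at least twice the ramp length")
        if self.lead < 0 or self.tail < 0:
            raise ValueError("lead and tail must be non-negative")
        if not (0 < self.segment_min <= self.segment_max):
            raise ValueError("need 0 < segment_min <= segment_max")


@dataclass(frozen=True)
class Stimulus:
    """A mixed trial waveform with its separately retained tracks."""

    mixed: np.ndarray = field(repr=False)
    target_track: np.ndarray = field(repr=False)
    masker_track: np.ndarray = field(repr=False)
    sample_rate: int
    target_onset: float
    tmr_db: float | str  # a number, or "baseline"
    voice_condition: str
    target_spec: SentenceSpec
    target_span: tuple[float, float] = (0.0, 0.0)  # (onset, offset) seconds

    @property
    def duration(self) -> float:
        return len(self.mixed) / self.sample_rate

    def measured_tmr_db(self) -> float:
        """20*log10(RMS_target / RMS_masker).

        The target RMS is taken over the target sentence extent (the track
        is zero-padded around it); the masker RMS over its full extent.
        """
        a = int(round(self.target_span[0] * self.sample_rate))
        b = int(round(self.target_span[1] * self.sample_rate))
        rt = rms(self.target_track[a:b] if b > a else self.target_track)
        rm = rms(self.masker_track)
        if rm == 0:
            return float("inf")
        return float(20.0 * np.log10(rt / rm))


def select_masker_sentences(
    target_spec: SentenceSpec,
    masker_corpus: Sequence[RenderedSentence],
    match_mode: str = "either",
) -> list[RenderedSentence]:
    """Masker sentences eligible for a given target.

    ``match_mode="either"`` (default) excludes masker sentences sharing
    either the colour or the number with the target; ``"both"`` excludes
    only sentences sharing both keywords.
    """
    if not masker_corpus:
        raise ValueError("masker corpus is empty")
    if match_mode not in ("either", "both"):
        raise ValueError(f"match_mode must be 'either' or 'both', got {match_mode!r}")
    out = []
    for sent in masker_corpus:
        same_colour = sent.spec.colour == target_spec.colour
        same_number = sent.spec.number == target_spec.number
        clash = (same_colour or same_number) if match_mode == "either" else (
            same_colour and same_number
        )
        if not clash:
            out.append(sent)
    if not out:
        raise ValueError("no eligible masker sentences after keyword exclusion")
    return out


def _raised_cosine_ramps(segment: np.ndarray, n_ramp: int) -> np.ndarray:
    """Apply raised-cosine (Hann half-window) on/off ramps in place-copy."""
    seg = segment.copy()
    if n_ramp <= 0 or 2 * n_ramp > seg.size:
        return seg
    win = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    seg[:n_ramp] *= win
    seg[-n_ramp:] *= win[::-1]
    return seg


def splice_masker(
    eligible_sentences: Sequence[RenderedSentence],
    target_duration: float,
    params: MaskerBuildParams = MaskerBuildParams(),
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Concatenate ramped random segments into a masker waveform.

    The result is exactly ``target_duration + lead + tail`` long (in samples
    at the corpus rate): segments are drawn until the total length is
    reached, then the concatenation is trimmed.
    """
    if not eligible_sentences:
        raise ValueError("eligible sentence set is empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sample_rate = eligible_sentences[0].sample_rate
    total_n = int(round(target_duration * sample_rate)) + int(
        round((params.lead + params.tail) * sample_rate)
    )
    durations = np.array([s.duration for s in eligible_sentences])
    if np.all(durations < params.segment_min):
        raise ValueError("every masker sentence is shorter than segment_min")
    pieces: list[np.ndarray] = []
    n_acc = 0
    while n_acc < total_n:
        i = int(rng.integers(len(eligible_sentences)))
        sent = eligible_sentences[i]
        # re-sample a feasible length when the sentence is shorter than the draw
        max_len = min(params.segment_max, sent.duration)
        if max_len < params.segment_min:
            continue
        seg_s = float(rng.uniform(params.segment_min, max_len))
        n_seg = int(round(seg_s * sample_rate))
        start_max = len(sent.samples) - n_seg
        start = int(rng.integers(start_max + 1))
        seg = sent.samples[start : start + n_seg]
        n_ramp = int(round(params.ramp * sample_rate))
        pieces.append(_raised_cosine_ramps(seg, n_ramp))
        n_acc += n_seg
    return np.concatenate(pieces)[:total_n]


def mix_at_tmr(
    target: RenderedSentence,
    masker: np.ndarray,
    tmr_db: float,
    params: MaskerBuildParams = MaskerBuildParams(),
    voice_condition: str = "same",
) -> Stimulus:
    """Mix a target into a masker at an exact broadband-RMS TMR.

    The target starts ``params.lead`` seconds into the masker.  If the mixed
    peak would exceed full scale, both tracks are scaled down jointly, which
    preserves the TMR.
    """
    sr = target.sample_rate
    rt = rms(target.samples)
    rm = rms(masker)
    if rt == 0 or rm == 0:
        raise ValueError("silent target or masker: TMR undefined")
    gain = (rt / rm) * 10.0 ** (-float(tmr_db) / 20.0)
    masker_track = masker * gain
    n_lead = int(round(params.lead * sr))
    target_track = np.zeros(len(masker_track))
    end = n_lead + len(target.samples)
    if end > len(target_track):
        raise ValueError("masker shorter than lead + target")
    target_track[n_lead:end] = target.samples
    mixed = target_track + masker_track
    peak = float(np.max(np.abs(mixed)))
    if peak > 1.0:
        scale = 0.999 / peak
        mixed = mixed * scale
        target_track = target_track * scale
        masker_track = masker_track * scale
    return Stimulus(
        mixed=mixed,
        target_track=target_track,
        masker_track=masker_track,
        sample_rate=sr,
        target_onset=params.lead,
        tmr_db=float(tmr_db),
        voice_condition=voice_condition,
        target_spec=target.spec,
        target_span=(params.lead, params.lead + target.duration),
    )


def baseline_stimulus(target: RenderedSentence) -> Stimulus:
    """Target with no masker at all (paradigm-check condition)."""
    silence = np.zeros_like(target.samples)
    return Stimulus(
        mixed=target.samples.copy(),
        target_track=target.samples.copy(),
        masker_track=silence,
        sample_rate=target.sample_rate,
        target_onset=0.0,
        tmr_db="baseline",
        voice_condition="baseline",
        target_spec=target.spec,
        target_span=(0.0, target.duration),
    )


def make_stimulus(
    target: RenderedSentence,
    masker_corpus: Sequence[RenderedSentence],
    tmr_db: float,
    voice_condition: str = "same",
    params: MaskerBuildParams = MaskerBuildParams(),
    rng: np.random.Generator | int = 0,
    match_mode: str = "either",
) -> Stimulus:
    """Select, splice and mix in one step."""
    eligible = select_masker_sentences(target.spec, masker_corpus, match_mode)
    masker = splice_masker(eligible, target.duration, params, rng)
    return mix_at_tmr(target, masker, tmr_db, params, voice_condition)
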