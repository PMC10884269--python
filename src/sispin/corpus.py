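"""Synthetic coordinate-response-measure (CRM) sentence corpus.

Each sentence follows the fixed template "Show the <call sign> where the
<colour> <number> is", with the call sign drawn from {dog, cat}, the colour
from six monosyllabic colour words and the number from the eight numbers
1-6, 8, 9 (disyllabic "seven" is excluded from the response set).  A corpus
is the full 6 x 8 colour-by-number cross for one call sign: 48 sentences.

Speech is emulated by parametric source-filter synthesis: keywords are
voiced vowel-like tokens (glottal pulse train with a gentle F0 declination
and per-pulse micro-jitter, filtered through a cascade of formant
resonators), while carrier words are unvoiced noise-burst fillers that carry
no scoring information.  Intelligibility is thus replaced by
machine-distinguishable formant patterns, which keeps the whole pipeline
deterministic and self-contained.  The reference voice has F0 242 Hz; F0 and
VTL manipulations rescale the pulse rate and the formant frequencies (see
:mod:`sispin.voice`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .voice import VoiceSpec

__all__ = [
    "CALL_SIGNS",
    "COLOURS",
    "NUMBERS",
    "KeywordToken",
    "SentenceSpec",
    "RenderedSentence",
    "keyword_token",
    "synthesize_keyword",
    "assemble_sentence",
    "build_corpus",
    "DEFAULT_SAMPLE_RATE",
]

DEFAULT_SAMPLE_RATE = 22050
MIN_SAMPLE_RATE = 16000

#: Inter-token silence inside a sentence.
TOKEN_GAP_S = 0.050

CALL_SIGNS = ("dog", "cat")
COLOURS = ("red", "green", "pink", "white", "black", "blue")
NUMBERS = ("1", "2", "3", "4", "5", "6", "8", "9")

# Distinct vowel-like formant patterns (centre Hz, bandwidth Hz) per keyword.
# Values span the vowel space so every keyword is spectrally separable.
_FORMANTS: dict[str, tuple[tuple[float, float], ...]] = {
    "dog": ((650, 90), (1100, 120), (2500, 160)),
    "cat": ((700, 90), (1800, 120), (2600, 160)),
    "red": ((600, 90), (1300, 120), (2400, 160)),
    "green": ((300, 80), (2300, 130), (3000, 170)),
    "pink": ((450, 85), (2000, 125), (2700, 160)),
    "white": ((750, 95), (1500, 120), (2500, 160)),
    "black": ((700, 90), (1250, 120), (2450, 160)),
    "blue": ((350, 80), (900, 110), (2300, 150)),
    "1": ((400, 85), (2100, 125), (2800, 165)),
    "2": ((380, 80), (1000, 115), (2350, 155)),
    "3": ((330, 80), (2200, 130), (2900, 170)),
    "4": ((550, 90), (950, 110), (2400, 155)),
    "5": ((620, 90), (1750, 125), (2550, 160)),
    "6": ((420, 85), (1900, 125), (2650, 160)),
    "8": ((580, 90), (1650, 120), (2500, 160)),
    "9": ((500, 85), (2050, 125), (2750, 165)),
}

_KEYWORD_DURATION_S = 0.25
_CARRIER_DURATION_S = 0.15
#: Words of the carrier template in order; None marks keyword slots.
_TEMPLATE: tuple[str | None, ...] = (
    "show", "the", "<call_sign>", "where", "the", "<colour>", "<number>", "is",
)

_KEYWORD_RMS = 0.06
_CARRIER_RMS = 0.025
_EDGE_TAPER_S = 0.010

#: Linear F0 declination over a voiced token (fraction of nominal; the track
#: runs from +decl to -decl so the median frame sits at the nominal F0).
_F0_DECLINATION = 0.02
#: Per-pulse timing jitter (fraction of the local period).
_PULSE_JITTER = 0.002
#: Aspiration (breath) noise amplitude relative to the pulse train; the
#: noise passes through the same formant filter, so the spectral envelope is
#: sampled continuously between harmonics.
_ASPIRATION = 0.2


@dataclass(frozen=True)
class KeywordToken:
    """One word of a CRM sentence with its synthesis recipe."""

    kind: str  # call_sign | colour | number | carrier
    label: str
    formant_pattern: tuple[tuple[float, float], ...]
    nominal_duration: float

    def __post_init__(self) -> None:
        closed = {"call_sign": CALL_SIGNS, "colour": COLOURS, "number": NUMBERS}
        if self.kind in closed and self.label not in closed[self.kind]:
            raise ValueError(
                f"unknown {self.kind} label {self.label!r}; "
                f"expected one of {closed[self.kind]}"
            )
        if self.kind not in (*closed, "carrier"):
            raise ValueError(f"unknown token kind {self.kind!r}")
        if not self.nominal_duration > 0:
            raise ValueError("nominal_duration must be positive")
        if self.kind != "carrier" and not self.formant_pattern:
            raise ValueError("voiced tokens need a non-empty formant pattern")

    @property
    def voiced(self) -> bool:
        return self.kind != "carrier"


def keyword_token(kind: str, label: str, duration: float | None = None) -> KeywordToken:
    """Look up the synthesis recipe for a keyword or carrier word.

    ``duration`` overrides the nominal token duration, e.g. for a long
    sustained probe token used in acoustic measurements.
    """
    if kind == "carrier":
        return KeywordToken("carrier", label, (), duration or _CARRIER_DURATION_S)
    if label not in _FORMANTS:
        closed = {"call_sign": CALL_SIGNS, "colour": COLOURS, "number": NUMBERS}
        expected = closed.get(kind, tuple(_FORMANTS))
        raise ValueError(f"unknown {kind} label {label!r}; expected one of {expected}")
    return KeywordToken(kind, label, _FORMANTS[label], duration or _KEYWORD_DURATION_S)


@dataclass(frozen=True)
class SentenceSpec:
    """Call-sign / colour / number triple plus the carrier template."""

    call_sign: str
    colour: str
    number: str
    carrier_template: tuple[str | None, ...] = _TEMPLATE

    def __post_init__(self) -> None:
        if self.call_sign not in CALL_SIGNS:
            raise ValueError(f"call sign must be one of {CALL_SIGNS}, got {self.call_sign!r}")
        if self.colour not in COLOURS:
            raise ValueError(f"colour must be one of {COLOURS}, got {self.colour!r}")
        if self.number not in NUMBERS:
            raise ValueError(f"number must be one of {NUMBERS}, got {self.number!r}")

    def tokens(self) -> list[KeywordToken]:
        out = []
        for word in self.carrier_template:
            if word == "<call_sign>":
                out.append(keyword_token("call_sign", self.call_sign))
            elif word == "<colour>":
                out.append(keyword_token("colour", self.colour))
            elif word == "<number>":
                out.append(keyword_token("number", self.number))
            else:
                out.append(keyword_token("carrier", word))
        return out

    def text(self) -> str:
        words = {"<call_sign>": self.call_sign, "<colour>": self.colour,
                 "<number>": self.number}
        return " ".join(words.get(w, w) for w in self.carrier_template)


@dataclass(frozen=True)
class RenderedSentence:
    """A synthesized sentence waveform with exact keyword metadata."""

    spec: SentenceSpec
    voice: VoiceSpec
    samples: np.ndarray = field(repr=False)
    sample_rate: int
    keyword_spans: Mapping[str, tuple[float, float]]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _resonator_sos(freq: float, bandwidth: float, sample_rate: float) -> np.ndarray:
    """Second-order section for one formant resonance."""
    r = np.exp(-np.pi * bandwidth / sample_rate)
    theta = 2 * np.pi * freq / sample_rate
    # unity gain at DC is irrelevant; tokens are RMS-normalised afterwards
    return np.array([[1.0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r]])


def _pulse_train(
    n_samples: int, f0: float, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Glottal impulse train with declination and micro-jitter."""
    out = np.zeros(n_samples)
    duration = n_samples / sample_rate
    t = 0.0
    while t < duration:
        frac = t / duration
        inst_f0 = f0 * (1.0 + _F0_DECLINATION * (1.0 - 2.0 * frac))
        period = 1.0 / inst_f0
        jitter = rng.normal(0.0, _PULSE_JITTER * period)
        idx = int(round((t + jitter) * sample_rate))
        if 0 <= idx < n_samples:
            out[idx] = 1.0
        t += period
    return out


def _edge_taper(x: np.ndarray, sample_rate: float) -> np.ndarray:
    n = min(int(round(_EDGE_TAPER_S * sample_rate)), x.size // 2)
    if n <= 0:
        return x
    win = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))
    x = x.copy()
    x[:n] *= win
    x[-n:] *= win[::-1]
    return x


def synthesize_keyword(
    token: KeywordToken,
    voice: VoiceSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render one token as a waveform.

    Voiced tokens are a glottal pulse train at the voice's (shifted) F0
    filtered through the token's formant resonators, with every formant
    frequency multiplied by the voice's VTL envelope ratio.  Carrier tokens
    are band-limited noise bursts.  Deterministic for a fixed seed.
    """
    if sample_rate < MIN_SAMPLE_RATE:
        raise ValueError(
            f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz, got {sample_rate}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = int(round(token.nominal_duration * sample_rate))
    if token.voiced:
        src = _pulse_train(n, voice.synthesis_f0, sample_rate, rng)
        # breathiness: noise power scaled to the pulse-train power (f0/fs)
        src = src + _ASPIRATION * np.sqrt(voice.synthesis_f0 / sample_rate) * (
            rng.standard_normal(n)
        )
        y = src
        scale = voice.formant_scale
        for freq, bw in token.formant_pattern:
            f_eff = min(freq * scale, 0.45 * sample_rate)
            y = sps.sosfilt(_resonator_sos(f_eff, bw, sample_rate), y)
        target_rms = _KEYWORD_RMS
    else:
        noise = rng.standard_normal(n)
        sos = sps.butter(4, [1000, 4000], btype="bandpass", fs=sample_rate, output="sos")
        y = sps.sosfilt(sos, noise)
        target_rms = _CARRIER_RMS
    r = float(np.sqrt(np.mean(np.square(y))))
    if r > 0:
        y = y * (target_rms / r)
    return _edge_taper(y, sample_rate)


def assemble_sentence(
    spec: SentenceSpec,
    voice: VoiceSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng_seed: int = 0,
    duration_band: tuple[float, float] = (1.5, 2.5),
) -> RenderedSentence:
    """Concatenate carrier and keyword tokens into one sentence.

    Tokens are separated by 50 ms gaps; ``keyword_spans`` records the exact
    (start, end) of the call-sign, colour and number tokens.  The span
    layout depends only on the sentence spec (jitter never moves a boundary).
    """
    tokens = spec.tokens()
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF])
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(tokens))]
    gap = np.zeros(int(round(TOKEN_GAP_S * sample_rate)))
    pieces: list[np.ndarray] = []
    spans: dict[str, tuple[float, float]] = {}
    cursor = 0
    for i, tok in enumerate(tokens):
        wav = synthesize_keyword(tok, voice, sample_rate, rngs[i])
        if tok.kind in ("call_sign", "colour", "number"):
            spans[tok.label] = (cursor / sample_rate, (cursor + wav.size) / sample_rate)
        pieces.append(wav)
        cursor += wav.size
        if i < len(tokens) - 1:
            pieces.append(gap)
            cursor += gap.size
    samples = np.concatenate(pieces)
    peak = np.max(np.abs(samples))
    if peak > 0.99:
        samples = samples * (0.99 / peak)
    duration = samples.size / sample_rate
    lo, hi = duration_band
    if not (lo <= duration <= hi):
        raise ValueError(
            f"sentence duration {duration:.3f}s outside configured band [{lo}, {hi}]s"
        )
    return RenderedSentence(spec, voice, samples, sample_rate, spans)


def build_corpus(
    call_sign: str,
    voice: VoiceSpec | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng_seed: int = 0,
) -> list[RenderedSentence]:
    """Render the full 48-sentence corpus (6 colours x 8 numbers) for one call sign."""
    if call_sign not in CALL_SIGNS:
        raise ValueError(f"call sign must be one of {CALL_SIGNS}, got {call_sign!r}")
    voice = voice or VoiceSpec()
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 1])
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(48)]
    out = []
    i = 0
    for colour in COLOURS:
        for number in NUMBERS:
            spec = SentenceSpec(call_sign, colour, number)
            out.append(assemble_sentence(spec, voice, sample_rate, child_seeds[i]))
            i += 1
    return out
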