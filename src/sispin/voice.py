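"""Voice specifications and semitone-based F0 / vocal-tract-length manipulation.

A voice is described by a reference fundamental frequency (F0, Hz) plus two
offsets expressed in semitones (st, 1/12 of an octave): ``delta_f0`` shifts
the glottal pulse rate, ``delta_vtl`` shifts the apparent vocal-tract length.
A positive ``delta_vtl`` means a *longer* vocal tract (a larger speaker) and
therefore multiplies all formant/envelope frequencies by ``2**(-delta/12)``;
this sign convention is documented rather than inferred, see docs/methods.md.

Manipulations are applied at the synthesis-parameter level: the corpus is
parametric, so a masker voice is simply re-synthesized with shifted
parameters rather than vocoded after the fact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "VoiceSpec",
    "VoiceCondition",
    "VOICE_CONDITIONS",
    "TRAINING_GRID",
    "REFERENCE_F0_HZ",
    "f0_ratio",
    "vtl_envelope_ratio",
    "apply_voice",
    "conditions_to_json",
    "conditions_from_json",
]

#: Reference F0 of the female speaker the corpus emulates.
REFERENCE_F0_HZ = 242.0


def f0_ratio(delta_st: float) -> float:
    """Multiplicative F0 factor for a semitone offset: ``2**(delta/12)``.

    Satisfies the group property ``f0_ratio(a + b) == f0_ratio(a) * f0_ratio(b)``.
    """
    delta_st = float(delta_st)
    if not math.isfinite(delta_st):
        raise ValueError(f"delta_f0 must be finite, got {delta_st!r}")
    return 2.0 ** (delta_st / 12.0)


def vtl_envelope_ratio(delta_st: float) -> float:
    """Multiplicative factor applied to formant/envelope frequencies.

    Positive ``delta_st`` lengthens the vocal tract, lowering all formants:
    the factor is ``2**(-delta/12)`` (e.g. +12 st halves every formant).
    """
    delta_st = float(delta_st)
    if not math.isfinite(delta_st):
        raise ValueError(f"delta_vtl must be finite, got {delta_st!r}")
    return 2.0 ** (-delta_st / 12.0)


@dataclass(frozen=True)
class VoiceSpec:
    """A (possibly manipulated) voice: reference F0 and semitone offsets."""

    f0_ref: float = REFERENCE_F0_HZ
    delta_f0: float = 0.0
    delta_vtl: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f0_ref > 0):
            raise ValueError(f"f0_ref must be positive, got {self.f0_ref!r}")
        for name in ("delta_f0", "delta_vtl"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def synthesis_f0(self) -> float:
        """Glottal pulse rate in Hz after the F0 shift."""
        return self.f0_ref * f0_ratio(self.delta_f0)

    @property
    def formant_scale(self) -> float:
        """Factor applied to every formant frequency after the VTL shift."""
        return vtl_envelope_ratio(self.delta_vtl)

    def shifted(self, delta_f0: float = 0.0, delta_vtl: float = 0.0) -> "VoiceSpec":
        return replace(
            self,
            delta_f0=self.delta_f0 + delta_f0,
            delta_vtl=self.delta_vtl + delta_vtl,
        )


@dataclass(frozen=True)
class VoiceCondition:
    """One of the masker voice conditions of the experimental design."""

    name: str
    delta_f0: float
    delta_vtl: float


#: The four masker voice conditions: the cross of dF0 in {0, -12} st and
#: dVTL in {0, +3.8} st.  "same" passes through the synthesis path unchanged
#: (resynthesis parity with the target).
VOICE_CONDITIONS: tuple[VoiceCondition, ...] = (
    VoiceCondition("same", 0.0, 0.0),
    VoiceCondition("f0", -12.0, 0.0),
    VoiceCondition("vtl", 0.0, 3.8),
    VoiceCondition("f0+vtl", -12.0, 3.8),
)

#: The 3 x 3 training grid of voice offsets (dF0 in {-12, -6, 0} st crossed
#: with dVTL in {0, +1.9, +3.8} st), from which training trials are drawn.
TRAINING_GRID: tuple[VoiceCondition, ...] = tuple(
    VoiceCondition(f"train_f0{df0:g}_vtl{dvtl:g}", df0, dvtl)
    for df0 in (-12.0, -6.0, 0.0)
    for dvtl in (0.0, 1.9, 3.8)
)


def apply_voice(base_voice: VoiceSpec, condition: VoiceCondition | str) -> VoiceSpec:
    """Return the masker ``VoiceSpec`` for one of the four voice conditions.

    The zero-offset condition still returns a spec routed through the same
    synthesis path, so synthesis artefacts match the target's.
    """
    if isinstance(condition, str):
        names = {c.name: c for c in VOICE_CONDITIONS}
        if condition not in names:
            raise ValueError(
                f"unknown voice condition {condition!r}; expected one of {sorted(names)}"
            )
        condition = names[condition]
    return replace(
        base_voice,
        delta_f0=condition.delta_f0,
        delta_vtl=condition.delta_vtl,
    )


def conditions_to_json(conditions: Iterable[VoiceCondition], path: str | Path) -> None:
    payload = [
        {"name": c.name, "delta_f0_st": c.delta_f0, "delta_vtl_st": c.delta_vtl}
        for c in conditions
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def conditions_from_json(path: str | Path) -> list[VoiceCondition]:
    payload = json.loads(Path(path).read_text())
    return [
        VoiceCondition(d["name"], float(d["delta_f0_st"]), float(d["delta_vtl_st"]))
        for d in payload
    ]
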