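"""File round-trips: WAV audio, JSON sidecars, session CSV logs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .corpus import RenderedSentence, SentenceSpec
from .masker import Stimulus
from .protocol import Condition, SessionResult, TrialResult

__all__ = [
    "write_wav",
    "read_wav",
    "write_sentence_bundle",
    "write_stimulus_bundle",
    "session_to_csv",
    "session_from_csv",
    "sessions_from_dir",
    "nars_to_csv",
    "nars_from_csv",
    "coding_to_csv",
    "coding_from_csv",
    "SessionCsvError",
]

_SESSION_COLUMNS = [
    "participant", "interface", "index", "tmr_db", "voice_condition",
    "target_colour", "target_number", "resp_colour", "resp_number",
    "correct", "t_present", "t_response", "t_feedback",
]


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int,
              bits: int = 16) -> None:
    """Write a float waveform as 16-bit PCM (default) or 32-bit float WAV."""
    samples = np.asarray(samples, dtype=float)
    if bits == 16:
        scaled = np.clip(samples, -1.0, 1.0)
        wavfile.write(path, sample_rate, (scaled * 32767.0).astype(np.int16))
    elif bits == 32:
        wavfile.write(path, sample_rate, samples.astype(np.float32))
    else:
        raise ValueError("bits must be 16 or 32")


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file back to a float waveform in [-1, 1]."""
    sample_rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        return data.astype(float) / 32767.0, int(sample_rate)
    return data.astype(float), int(sample_rate)


def write_sentence_bundle(sentence: RenderedSentence, stem: str | Path) -> None:
    """WAV plus JSON sidecar (spec, voice, spans) for one rendered sentence."""
    stem = Path(stem)
    write_wav(stem.with_suffix(".wav"), sentence.samples, sentence.sample_rate)
    sidecar = {
        "call_sign": sentence.spec.call_sign,
        "colour": sentence.spec.colour,
        "number": sentence.spec.number,
        "voice": asdict(sentence.voice),
        "sample_rate": sentence.sample_rate,
        "keyword_spans": {k: list(v) for k, v in sentence.keyword_spans.items()},
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_stimulus_bundle(stim: Stimulus, stem: str | Path,
                          include_tracks: bool = True) -> None:
    """Mixed WAV (optionally the separate tracks) plus a JSON sidecar."""
    stem = Path(stem)
    write_wav(stem.with_suffix(".wav"), stim.mixed, stim.sample_rate)
    if include_tracks:
        write_wav(stem.parent / f"{stem.name}_target.wav", stim.target_track,
                  stim.sample_rate)
        write_wav(stem.parent / f"{stem.name}_masker.wav", stim.masker_track,
                  stim.sample_rate)
    sidecar = {
        "tmr_db": stim.tmr_db,
        "voice_condition": stim.voice_condition,
        "target_onset_s": stim.target_onset,
        "sample_rate": stim.sample_rate,
        "target": {
            "call_sign": stim.target_spec.call_sign,
            "colour": stim.target_spec.colour,
            "number": stim.target_spec.number,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


class SessionCsvError(ValueError):
    """Malformed session CSV; the message names the offending line."""


def session_to_csv(session: SessionResult, path: str | Path) -> None:
    """One row per logged trial, stable column order."""
    rows = []
    for t in session.trials:
        rows.append(
            {
                "participant": session.participant_id,
                "interface": session.interface,
                "index": t.index,
                "tmr_db": "baseline" if t.condition.baseline else t.condition.tmr_db,
                "voice_condition": "baseline" if t.condition.baseline else t.condition.voice,
                "target_colour": t.target[0],
                "target_number": t.target[1],
                "resp_colour": t.response[0],
                "resp_number": t.response[1],
                "correct": int(t.correct),
                "t_present": t.present_time,
                "t_response": t.response_time,
                "t_feedback": t.feedback_time,
            }
        )
    pd.DataFrame(rows, columns=_SESSION_COLUMNS).to_csv(path, index=False)


def session_from_csv(path: str | Path) -> SessionResult:
    """Rebuild a SessionResult from its CSV log (lossless round-trip)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SessionCsvError(f"{path}: empty file")
    header = lines[0].split(",")
    missing = set(_SESSION_COLUMNS) - set(header)
    if missing:
        raise SessionCsvError(f"{path}: line 1: missing columns {sorted(missing)}")
    col = {name: header.index(name) for name in _SESSION_COLUMNS}
    trials: list[TrialResult] = []
    participant, interface = None, None
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise SessionCsvError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        try:
            participant = parts[col["participant"]]
            interface = parts[col["interface"]]
            tmr_raw = parts[col["tmr_db"]]
            if tmr_raw == "baseline":
                condition = Condition(None, None, baseline=True)
            else:
                condition = Condition(float(tmr_raw), parts[col["voice_condition"]])
            trials.append(
                TrialResult(
                    index=int(parts[col["index"]]),
                    condition=condition,
                    target=(parts[col["target_colour"]], parts[col["target_number"]]),
                    response=(parts[col["resp_colour"]], parts[col["resp_number"]]),
                    correct=bool(int(parts[col["correct"]])),
                    present_time=float(parts[col["t_present"]]),
                    response_time=float(parts[col["t_response"]]),
                    feedback_time=float(parts[col["t_feedback"]]),
                )
            )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, SessionCsvError):
                raise
            raise SessionCsvError(f"{path}: line {lineno}: {exc}") from exc
    if participant is None:
        raise SessionCsvError(f"{path}: no trial rows")
    return SessionResult(participant_id=participant, interface=interface,
                         trials=trials)


def sessions_from_dir(directory: str | Path) -> list[tuple[SessionResult, SessionResult]]:
    """Load every session CSV in a directory, paired by participant.

    Returns (computer, robot) pairs; participants missing either interface
    are rejected, since the analyses are repeated-measures.
    """
    directory = Path(directory)
    by_participant: dict[str, dict[str, SessionResult]] = {}
    for path in sorted(directory.glob("*.csv")):
        sess = session_from_csv(path)
        by_participant.setdefault(sess.participant_id, {})[sess.interface] = sess
    pairs = []
    for pid, sessions in sorted(by_participant.items()):
        if set(sessions) != {"computer", "robot"}:
            raise ValueError(
                f"participant {pid}: need one computer and one robot session, "
                f"found {sorted(sessions)}"
            )
        pairs.append((sessions["computer"], sessions["robot"]))
    if not pairs:
        raise ValueError(f"no session CSVs found in {directory}")
    return pairs


def nars_to_csv(responses: np.ndarray, path: str | Path) -> None:
    """Questionnaire matrix as CSV: respondent id plus 14 item columns."""
    arr = np.asarray(responses, dtype=int)
    cols = ["id"] + [f"item{i + 1:02d}" for i in range(arr.shape[1])]
    df = pd.DataFrame(
        np.column_stack([np.arange(arr.shape[0]), arr]), columns=cols
    )
    df.to_csv(path, index=False)


def nars_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    items = [c for c in df.columns if c.startswith("item")]
    if len(items) != 14:
        raise ValueError(f"{path}: expected 14 item columns, found {len(items)}")
    return df[items].to_numpy(dtype=int)


def coding_to_csv(records, path: str | Path) -> None:
    """Long-format behaviour counts: coder, segment, interface, behaviour, count."""
    rows = []
    for r in records:
        for behaviour, count in r.counts.items():
            rows.append(
                {
                    "coder": r.coder_id,
                    "segment": r.segment_id,
                    "interface": r.interface,
                    "behaviour": behaviour,
                    "count": count,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def coding_from_csv(path: str | Path):
    from .listener import CodingRecord

    df = pd.read_csv(path)
    needed = {"coder", "segment", "interface", "behaviour", "count"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    records = []
    for (coder, segment, interface), grp in df.groupby(
        ["coder", "segment", "interface"], sort=True
    ):
        counts = dict(zip(grp["behaviour"], grp["count"].astype(int)))
        records.append(
            CodingRecord(
                coder_id=str(coder), segment_id=str(segment),
                interface=str(interface), counts=counts,
            )
        )
    return records
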