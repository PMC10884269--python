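"""Acoustic calibration: speech-shaped noise, third-octave levels, dB SPL.

The package has no microphone, so sound pressure level exists only under a
declared digital reference convention: a full-scale sine (peak 1.0, RMS
1/sqrt(2)) is defined to play at ``FULL_SCALE_SINE_DB_SPL`` (default 100 dB
SPL).  Under that convention the calibrated presentation level of 65 dB SPL
is computable and testable in software.

Third-octave band levels use the IEC base-2 series (centres 1000 * 2**(k/3)
Hz); band powers are integrated from a Welch spectrum, so summing the band
powers conserves total power across the covered range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .acoustics import rms

__all__ = [
    "FULL_SCALE_SINE_DB_SPL",
    "BandSpectrum",
    "third_octave_centres",
    "average_spectrum",
    "shape_noise",
    "third_octave_levels",
    "waveform_level_db_spl",
    "set_overall_level",
]

#: Digital full-scale sine reference, in dB SPL.
FULL_SCALE_SINE_DB_SPL = 100.0
_FS_SINE_RMS = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class BandSpectrum:
    """Third-octave band levels plus the overall level, all in dB."""

    centres_hz: np.ndarray
    levels_db: np.ndarray
    overall_db: float

    def __post_init__(self) -> None:
        if len(self.centres_hz) != len(self.levels_db):
            raise ValueError("centres and levels must have equal length")

    def summed_level_db(self) -> float:
        """Power sum of the band levels (should match overall_db)."""
        finite = np.isfinite(self.levels_db)
        return float(10.0 * np.log10(np.sum(10.0 ** (self.levels_db[finite] / 10.0))))


def third_octave_centres(fmin: float = 100.0, fmax: float = 8000.0) -> np.ndarray:
    """IEC base-2 third-octave centre frequencies covering [fmin, fmax]."""
    k = np.arange(-30, 31)
    centres = 1000.0 * 2.0 ** (k / 3.0)
    # a 5% tolerance keeps the band whose *nominal* frequency is fmin
    # (e.g. the nominal 100 Hz band has an exact base-2 centre of 99.2 Hz)
    return centres[(centres >= fmin * 0.95) & (centres <= fmax * 1.05)]


def average_spectrum(
    corpus: list[np.ndarray] | list, sample_rate: int | None = None, nperseg: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Long-term average power spectrum of a sentence corpus.

    Accepts either rendered sentences (with ``samples``/``sample_rate``
    attributes) or raw waveforms plus ``sample_rate``.  Returns
    (frequencies, mean Welch power density), the average weighted by
    duration across the corpus.
    """
    if not corpus:
        raise ValueError("empty corpus")
    waves = []
    for item in corpus:
        if hasattr(item, "samples"):
            waves.append(np.asarray(item.samples, dtype=float))
            sample_rate = int(item.sample_rate)
        else:
            waves.append(np.asarray(item, dtype=float))
    if sample_rate is None:
        raise ValueError("sample_rate required for raw waveforms")
    f = None
    acc = None
    total = 0
    for w in waves:
        f, p = sps.welch(w, sample_rate, nperseg=min(nperseg, w.size))
        acc = p * w.size if acc is None else acc + p * w.size
        total += w.size
    return f, acc / total


def shape_noise(
    spectrum: tuple[np.ndarray, np.ndarray],
    duration: float,
    sample_rate: int,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to a target power spectrum.

    White Gaussian noise is filtered in the frequency domain by the square
    root of the target power spectrum (interpolated onto the FFT grid), so
    its long-term spectrum matches the target's shape.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f_t, p_t = spectrum
    n = int(round(duration * sample_rate))
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    mag = np.interp(freqs, f_t, np.sqrt(np.maximum(p_t, 0.0)))
    shaped = np.fft.irfft(spec * mag, n)
    r = rms(shaped)
    if r > 0:
        shaped = shaped * (0.05 / r)
    return shaped


def third_octave_levels(
    waveform: np.ndarray,
    sample_rate: int,
    fmin: float = 100.0,
    fmax: float = 8000.0,
    nperseg: int = 4096,
) -> BandSpectrum:
    """Third-octave band analysis of a waveform.

    Band powers are integrated from the Welch power spectral density over
    each band's edges (centre * 2**(+-1/6)); the overall level is the power
    sum over the covered range.  Silent bands sit at the numerical floor.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    f, p = sps.welch(x, sample_rate, nperseg=min(nperseg, x.size))
    df = f[1] - f[0]
    centres = third_octave_centres(fmin, fmax)
    levels = np.empty(len(centres))
    ref_power = _FS_SINE_RMS**2
    for i, fc in enumerate(centres):
        lo, hi = fc * 2.0 ** (-1.0 / 6.0), fc * 2.0 ** (1.0 / 6.0)
        sel = (f >= lo) & (f < hi)
        power = float(np.sum(p[sel]) * df)
        if power <= 0:
            levels[i] = -np.inf
        else:
            levels[i] = FULL_SCALE_SINE_DB_SPL + 10.0 * np.log10(power / ref_power)
    finite = np.isfinite(levels)
    if not np.any(finite):
        warnings.warn("silent input: all bands at the floor", stacklevel=2)
        overall = -np.inf
    else:
        overall = float(
            10.0 * np.log10(np.sum(10.0 ** (levels[finite] / 10.0)))
        )
    return BandSpectrum(centres, levels, overall)


def waveform_level_db_spl(waveform: np.ndarray) -> float:
    """Broadband level of a waveform under the digital SPL convention."""
    r = rms(waveform)
    if r <= 0:
        return float("-inf")
    return FULL_SCALE_SINE_DB_SPL + 20.0 * np.log10(r / _FS_SINE_RMS)


def set_overall_level(
    waveform: np.ndarray, target_db_spl: float = 65.0
) -> np.ndarray:
    """Scale a waveform so its broadband level equals ``target_db_spl``.

    Round-tripping through :func:`waveform_level_db_spl` returns the target
    to within numerical precision.  If the required gain would clip, the
    result is scaled to peak at full scale instead and a warning is issued.
    """
    x = np.asarray(waveform, dtype=float)
    current = waveform_level_db_spl(x)
    if not np.isfinite(current):
        raise ValueError("cannot set the level of a silent waveform")
    gain = 10.0 ** ((target_db_spl - current) / 20.0)
    out = x * gain
    peak = float(np.max(np.abs(out)))
    if peak > 1.0:
        warnings.warn(
            f"target level {target_db_spl} dB SPL clips at the digital ceiling; "
            "scaled to full-scale peak instead",
            stacklevel=2,
        )
        out = out / peak
    return out
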