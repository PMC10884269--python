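"""Acoustic measurement utilities: F0 tracking, formant estimation, levels.

These estimators are deliberately independent of the synthesis path: the F0
tracker works on frame-wise autocorrelation, the formant estimator on linear
prediction, and segmentation on short-time energy.  They serve both the
analysis/calibration code and the test oracles.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy import signal as sps

__all__ = [
    "rms",
    "level_db",
    "frame_signal",
    "estimate_f0",
    "estimate_f0_median",
    "estimate_formant",
    "energy_segments",
]


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a waveform."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.square(x))))


def level_db(x: np.ndarray, ref: float = 1.0) -> float:
    """RMS level in dB re ``ref`` (-inf for silence)."""
    r = rms(x)
    if r <= 0.0:
        return float("-inf")
    return 20.0 * np.log10(r / ref)


def frame_signal(
    x: np.ndarray, sample_rate: float, frame_s: float = 0.04, hop_s: float = 0.01
) -> np.ndarray:
    """Slice a waveform into overlapping frames (frames x samples)."""
    x = np.asarray(x, dtype=float)
    n = int(round(frame_s * sample_rate))
    hop = int(round(hop_s * sample_rate))
    if x.size < n:
        return np.empty((0, n))
    starts = np.arange(0, x.size - n + 1, hop)
    return np.stack([x[s : s + n] for s in starts])


def _autocorr_f0(frame: np.ndarray, sample_rate: float, fmin: float, fmax: float) -> float:
    """F0 of one frame from the autocorrelation peak, with parabolic refinement.

    Returns NaN when no acceptable peak exists (unvoiced/aperiodic frame).
    """
    frame = frame - np.mean(frame)
    if not np.any(frame):
        return float("nan")
    ac = sps.correlate(frame, frame, mode="full")
    ac = ac[ac.size // 2 :]
    if ac[0] <= 0:
        return float("nan")
    ac = ac / ac[0]
    lag_min = max(2, int(np.floor(sample_rate / fmax)))
    lag_max = int(np.ceil(sample_rate / fmin))
    if lag_max >= ac.size:
        lag_max = ac.size - 1
    if lag_min >= lag_max:
        return float("nan")
    seg = ac[lag_min : lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] < 0.3:  # too aperiodic to call voiced
        return float("nan")
    # parabolic interpolation around the peak for sub-sample lag
    if 1 <= k < ac.size - 1:
        a, b, c = ac[k - 1], ac[k], ac[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(sample_rate / (k + delta))


def estimate_f0(
    x: np.ndarray,
    sample_rate: float,
    fmin: float = 60.0,
    fmax: float = 500.0,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    energy_quantile: float = 0.5,
) -> np.ndarray:
    """Frame-wise F0 track over voiced frames (autocorrelation method).

    Frames below the ``energy_quantile`` of the frame-energy distribution are
    treated as unvoiced and skipped, as are frames without a clear
    autocorrelation peak.  Returns the array of per-frame F0 values in Hz.
    """
    frames = frame_signal(x, sample_rate, frame_s, hop_s)
    if frames.shape[0] == 0:
        return np.empty(0)
    energies = np.sqrt(np.mean(np.square(frames), axis=1))
    thresh = np.quantile(energies, energy_quantile)
    out = []
    for frame, e in zip(frames, energies):
        if e < thresh or e <= 0:
            continue
        f0 = _autocorr_f0(frame, sample_rate, fmin, fmax)
        if np.isfinite(f0):
            out.append(f0)
    return np.asarray(out)


def estimate_f0_median(x: np.ndarray, sample_rate: float, **kwargs) -> float:
    """Median F0 over voiced frames; NaN if nothing voiced was found."""
    track = estimate_f0(x, sample_rate, **kwargs)
    if track.size == 0:
        return float("nan")
    return float(np.median(track))


def estimate_formant(
    x: np.ndarray,
    sample_rate: float,
    fmin: float,
    fmax: float,
    f0: float | None = None,
    nperseg: int = 2048,
) -> float:
    """Frequency of the strongest spectral-envelope resonance in [fmin, fmax].

    Voiced speech has a line spectrum that samples the vocal-tract envelope
    only at harmonics of F0, which biases naive peak picking.  This
    estimator instead reads the envelope off the *noise floor* between
    harmonics (the aspiration component of voicing passes through the same
    vocal-tract filter): Welch log-PSD bins within a guard band of each
    harmonic are excluded, and a single-resonance magnitude model with a
    log-linear tilt is least-squares fitted to the remaining bins around the
    coarse peak.  Returns the fitted resonance centre frequency in Hz.
    """
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = estimate_f0_median(x, sample_rate)
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError("could not establish an F0 for harmonic masking")
    f, p = sps.welch(x, sample_rate, nperseg=nperseg, noverlap=nperseg // 2)
    df = f[1] - f[0]
    logp = np.log(p + 1e-30)
    unmasked = np.ones_like(p, dtype=bool)
    for k in range(1, int(f[-1] / f0) + 1):
        # guard covers the window main lobe plus the F0 declination spread
        unmasked &= np.abs(f - k * f0) > (2.5 * df + 0.025 * k * f0)
    interp = logp.copy()
    interp[~unmasked] = np.interp(f[~unmasked], f[unmasked], logp[unmasked])
    w = max(1, int(60.0 / df))
    smooth = np.convolve(interp, np.ones(w) / w, mode="same")
    band = (f >= fmin) & (f <= fmax)
    if not np.any(band):
        return float("nan")
    c0 = float(f[band][np.argmax(smooth[band])])
    sel = unmasked & (np.abs(f - c0) < 300.0) & (f > 60.0)
    if sel.sum() < 8:
        return c0
    fsel, ysel = f[sel], logp[sel]

    def model(fr, k, tilt, c, g):
        return k + tilt * (fr - c0) / 1000.0 - np.log((fr**2 - c**2) ** 2 + (g * fr) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            model,
            fsel,
            ysel,
            p0=[float(ysel.mean() + np.log((c0 * 100.0) ** 2)), 0.0, c0, 100.0],
            maxfev=20000,
        )
    except RuntimeError:
        return c0
    return float(abs(popt[2]))


def energy_segments(
    x: np.ndarray,
    sample_rate: float,
    frame_s: float = 0.005,
    rel_threshold: float = 0.05,
    min_gap_s: float = 0.02,
) -> list[tuple[float, float]]:
    """Active (high-energy) regions of a waveform as (start_s, end_s) pairs.

    Frames whose RMS exceeds ``rel_threshold`` times the peak frame RMS are
    active; active runs closer than ``min_gap_s`` are merged.  Used as an
    independent segmentation oracle for keyword span metadata.
    """
    n = max(1, int(round(frame_s * sample_rate)))
    n_frames = int(np.ceil(len(x) / n))
    pad = np.zeros(n_frames * n)
    pad[: len(x)] = np.asarray(x, dtype=float)
    frames = pad.reshape(n_frames, n)
    e = np.sqrt(np.mean(np.square(frames), axis=1))
    if e.max() <= 0:
        return []
    active = e > rel_threshold * e.max()
    segs: list[list[float]] = []
    for i, on in enumerate(active):
        t0, t1 = i * frame_s, (i + 1) * frame_s
        if on:
            if segs and t0 - segs[-1][1] <= min_gap_s:
                segs[-1][1] = t1
            else:
                segs.append([t0, t1])
    return [(s, min(e_, len(x) / sample_rate)) for s, e_ in segs]
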