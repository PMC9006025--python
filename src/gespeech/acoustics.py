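"""Speech acoustics: amplitude envelope, intensity, F0 and per-grade means.

The envelope is the magnitude of the analytic signal, low-passed at 8 Hz
and resampled to a fixed analysis rate — a standard operationalisation of
the slow (syllabic-rate) amplitude modulation used for speech-gesture
coupling.  Intensity is framewise mean-square power in dB re 2e-5 on the
normalised full scale (absolute calibration is irrelevant: every analysis
is a within-recording contrast).  F0 comes from a normalised
autocorrelation tracker with parabolic peak interpolation, voiced when the
autocorrelation peak strength reaches 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .io_formats import (
    SPEECH_ONLY,
    SPEECH_WITH_GESTURE,
    BlurSchedule,
    logger,
)

#: dB reference on normalised full scale (2e-5 "Pa-equivalent").
DB_REF = 2e-5
#: envelope low-pass cutoff (Hz)
ENVELOPE_CUTOFF_HZ = 8.0
#: default envelope output rate (Hz)
ENVELOPE_RATE_HZ = 100.0
#: intensity framing
INTENSITY_FRAME_S = 0.030
INTENSITY_HOP_S = 0.010
#: F0 search band and voicing threshold
F0_MIN_HZ, F0_MAX_HZ = 75.0, 500.0
VOICING_THRESHOLD = 0.45


@dataclass
class AcousticSeries:
    """Time-aligned acoustic measurements at the envelope analysis rate."""

    times: np.ndarray
    envelope: np.ndarray
    intensity_db: np.ndarray
    f0_hz: np.ndarray          # NaN where unvoiced
    modality: np.ndarray | None = None


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV (16-bit or float) as float in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if data.dtype.kind == "i":
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, float(rate)


def write_wav(path, samples: np.ndarray, rate: float) -> None:
    wavfile.write(path, int(rate), np.asarray(samples, dtype=np.float32))


def amplitude_envelope(
    samples: np.ndarray,
    rate: float,
    target_rate: float = ENVELOPE_RATE_HZ,
    cutoff_hz: float = ENVELOPE_CUTOFF_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Speech amplitude envelope at ``target_rate``.

    Magnitude of the analytic (Hilbert) signal, low-passed at ``cutoff_hz``
    with a zero-phase Butterworth filter, then linearly resampled.  Returns
    ``(times, envelope)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty audio")
    if np.abs(samples).max() > 1.0 + 1e-6:
        logger.warning("audio exceeds full scale; envelope may be clipped")
    env = np.abs(signal.hilbert(samples - samples.mean()))
    b, a = signal.butter(4, cutoff_hz / (0.5 * rate))
    env = signal.filtfilt(b, a, env)
    env = np.clip(env, 0.0, None)
    duration = samples.size / rate
    times = np.arange(0.0, duration, 1.0 / target_rate)
    src_t = np.arange(samples.size) / rate
    return times, np.interp(times, src_t, env)


def _frame_view(samples: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n = 1 + max(0, (samples.size - frame)) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return samples[idx]


def intensity_track(
    samples: np.ndarray,
    rate: float,
    frame_s: float = INTENSITY_FRAME_S,
    hop_s: float = INTENSITY_HOP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Framewise intensity 10*log10(mean-square / ref^2) in dB.

    30 ms frames at a 10 ms hop by default; frame timestamps are frame
    centres.  All-zero frames come out -inf.
    """
    samples = np.asarray(samples, dtype=float)
    frame = max(2, int(round(frame_s * rate)))
    hop = max(1, int(round(hop_s * rate)))
    if samples.size < frame:
        samples = np.pad(samples, (0, frame - samples.size))
    frames = _frame_view(samples, frame, hop)
    ms = np.mean(frames**2, axis=1)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(ms / DB_REF**2)
    times = (np.arange(frames.shape[0]) * hop + frame / 2) / rate
    return times, db


def max_intensity_db(
    samples: np.ndarray, rate: float, window: tuple[float, float] | None = None
) -> float:
    """Maximum framewise intensity (dB) in ``window`` (whole signal if None)."""
    times, db = intensity_track(samples, rate)
    if window is not None:
        w0, w1 = window
        if w0 < 0 or w1 > samples.size / rate + 1e-9:
            raise ValueError("intensity window outside the audio")
        sel = (times >= w0) & (times <= w1)
        db = db[sel]
    if db.size == 0 or not np.isfinite(db).any():
        logger.warning("silent window: intensity undefined (-inf)")
        return -np.inf
    return float(np.max(db))


def f0_track(
    samples: np.ndarray,
    rate: float,
    fmin: float = F0_MIN_HZ,
    fmax: float = F0_MAX_HZ,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation F0 track bounded to [fmin, fmax]; NaN when unvoiced.

    Per frame: remove the mean, compute the biased normalised
    autocorrelation, take its maximum over lags in [1/fmax, 1/fmin] with
    parabolic interpolation; the frame is voiced when that normalised peak
    reaches ``voicing_threshold``.
    """
    samples = np.asarray(samples, dtype=float)
    frame = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    if frame <= lag_max:
        frame = lag_max + 2
    if samples.size < frame:
        return np.array([]), np.array([])
    frames = _frame_view(samples, frame, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    n = frames.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]
    e0 = ac[:, 0].copy()
    quiet = e0 < 1e-12
    e0[quiet] = 1.0
    ac = ac / e0[:, None]
    f0 = np.full(frames.shape[0], np.nan)
    for i in range(frames.shape[0]):
        if quiet[i]:
            continue
        seg = ac[i, lag_min : lag_max + 1]
        j = int(np.argmax(seg))
        peak = seg[j]
        if peak < voicing_threshold:
            continue
        lag = lag_min + j
        # parabolic interpolation around the autocorrelation peak
        if 0 < j < seg.size - 1:
            y0, y1, y2 = seg[j - 1], seg[j], seg[j + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (y0 - y2) / denom
        f0[i] = rate / lag
    times = (np.arange(frames.shape[0]) * hop + frame / 2) / rate
    return times, f0


def max_f0(
    samples: np.ndarray,
    rate: float,
    window: tuple[float, float] | None = None,
    fmin: float = F0_MIN_HZ,
    fmax: float = F0_MAX_HZ,
) -> float:
    """Maximum F0 (Hz) over voiced frames in ``window``; NaN if unvoiced."""
    times, f0 = f0_track(samples, rate, fmin, fmax)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        f0 = f0[sel]
    voiced = f0[np.isfinite(f0)]
    return float(np.max(voiced)) if voiced.size else np.nan


def analyze_wav(
    samples: np.ndarray,
    rate: float,
    target_rate: float = ENVELOPE_RATE_HZ,
) -> AcousticSeries:
    """Envelope + intensity + F0 resampled onto one common time base."""
    times, env = amplitude_envelope(samples, rate, target_rate)
    it, idb = intensity_track(samples, rate)
    ft, f0 = f0_track(samples, rate)
    idb_i = np.interp(times, it, idb) if it.size else np.full_like(times, -np.inf)
    if ft.size:
        f0_i = np.interp(times, ft, f0)
        # do not let interpolation invent voicing across unvoiced frames
        voiced_i = np.interp(times, ft, np.isfinite(f0).astype(float)) > 0.99
        f0_i[~voiced_i] = np.nan
    else:
        f0_i = np.full_like(times, np.nan)
    return AcousticSeries(times=times, envelope=env, intensity_db=idb_i, f0_hz=f0_i)


def acoustics_by_grade(
    series: AcousticSeries,
    schedule: BlurSchedule,
    participant_id: str = "",
    dyad_id: str = "",
) -> pd.DataFrame:
    """Mean intensity and F0 per blur grade x modality.

    Requires ``series.modality`` (see ``io_formats.assign_modality``).
    Grade x modality cells with no voiced samples contribute no row
    (missing, not zero).
    """
    if series.modality is None:
        raise ValueError("assign modality labels before per-grade aggregation")
    grades = np.asarray(schedule.grade_of(series.times))
    rows = []
    for grade in range(1, schedule.n_grades + 1):
        for modality in (SPEECH_ONLY, SPEECH_WITH_GESTURE):
            sel = (grades == grade) & (series.modality == modality)
            if not sel.any():
                logger.info("grade %d %s: no voiced samples", grade, modality)
                continue
            inten = series.intensity_db[sel]
            inten = inten[np.isfinite(inten)]
            f0 = series.f0_hz[sel]
            f0 = f0[np.isfinite(f0)]
            rows.append(
                {
                    "participant": participant_id,
                    "dyad": dyad_id,
                    "grade": grade,
                    "modality": modality,
                    "mean_intensity_db": float(inten.mean()) if inten.size else np.nan,
                    "mean_f0_hz": float(f0.mean()) if f0.size else np.nan,
                    "n_samples": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
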