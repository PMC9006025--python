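"""System-level speech-gesture coupling via wavelet coherence.

Hand speed and the speech amplitude envelope are merged onto a common
grid, decomposed with a complex Morlet continuous wavelet transform, and
compared cell-by-cell in the 2-8 Hz band (syllabic timescales of
125-500 ms).  Coherence is the smoothed cross-spectrum magnitude
normalised by the smoothed auto-spectra; the cross-spectrum phase, scaled
by each cell's own frequency, gives the speech-gesture asynchrony in ms
(positive = speech leads).  Cell-level significance comes from
phase-randomised surrogates of the speech stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

#: analysis band (Hz); 2-8 Hz <=> 125-500 ms periods
DEFAULT_BAND = (2.0, 8.0)
#: Morlet centre frequency for omega0 = 6 (cycles per unit time)
MORLET_OMEGA0 = 6.0
_MORLET_FC = MORLET_OMEGA0 / (2.0 * np.pi)
_WAVELET = f"cmor2.0-{_MORLET_FC:.12f}"
#: scales per octave of the frequency grid
SCALES_PER_OCTAVE = 12
#: default surrogate count / threshold for the significance test
N_SURROGATES = 300
P_THRESHOLD = 0.05
#: minimum merged sample rate (Hz)
MIN_MERGE_RATE = 32.0


class DegenerateSeriesError(ValueError):
    """A constant series cannot be z-scored or meaningfully compared."""


@dataclass
class MergedPair:
    """Speech envelope and hand speed on a common grid, z-scored."""

    times: np.ndarray
    speech: np.ndarray
    gesture: np.ndarray
    rate: float


@dataclass
class CrossWaveletResult:
    """Time-frequency coherence and phase for one merged pair."""

    times: np.ndarray
    freqs: np.ndarray            # Hz, descending period order not guaranteed
    coherence: np.ndarray        # (n_freqs, n_times) in [0, 1]
    phase: np.ndarray            # radians, phase of S(Wspeech * conj(Wgesture))
    band: tuple[float, float]

    @property
    def periods_ms(self) -> np.ndarray:
        return 1000.0 / self.freqs


@dataclass
class CoherenceResult:
    """Per-event summary over statistically reliable cells."""

    event_ref: str
    band: tuple[float, float]
    coherence: float
    phase_asynchrony_ms: float
    n_significant_cells: int
    p_threshold: float = P_THRESHOLD


# ---------------------------------------------------------------------------


def merge_streams(
    speech: tuple[np.ndarray, np.ndarray],
    gesture: tuple[np.ndarray, np.ndarray],
    rate: float = 2 * MIN_MERGE_RATE,
) -> MergedPair:
    """Resample both streams onto a common grid and z-score each.

    Parameters are ``(times, values)`` pairs; the common grid spans their
    overlapping support at ``rate`` Hz (>= 32 Hz).  Raises when one stream
    does not cover the other's window or a stream is constant.
    """
    if rate < MIN_MERGE_RATE:
        raise ValueError(f"merge rate must be >= {MIN_MERGE_RATE} Hz")
    (ts, vs), (tg, vg) = speech, gesture
    t0 = max(ts[0], tg[0])
    t1 = min(ts[-1], tg[-1])
    if t1 - t0 <= 0:
        raise ValueError("speech and gesture streams do not overlap in time")
    span = max(ts[-1], tg[-1]) - min(ts[0], tg[0])
    if (t1 - t0) < 0.95 * span:
        raise ValueError("coverage gap: streams overlap on <95% of the window")
    grid = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    out = []
    for t, v in ((ts, vs), (tg, vg)):
        y = np.interp(grid, t, v)
        sd = y.std()
        if sd < 1e-12:
            raise DegenerateSeriesError("constant stream cannot be z-scored")
        out.append((y - y.mean()) / sd)
    return MergedPair(times=grid, speech=out[0], gesture=out[1], rate=rate)


def band_frequencies(
    band: tuple[float, float] = DEFAULT_BAND,
    scales_per_octave: int = SCALES_PER_OCTAVE,
) -> np.ndarray:
    """Geometric frequency grid whose extremes are exactly the band edges."""
    f0, f1 = band
    n_oct = np.log2(f1 / f0)
    n = max(2, int(round(n_oct * scales_per_octave)) + 1)
    return f0 * 2.0 ** (np.linspace(0.0, n_oct, n))


def _cwt(x: np.ndarray, rate: float, freqs: np.ndarray) -> np.ndarray:
    scales = _MORLET_FC * rate / freqs
    coefs, _ = pywt.cwt(x, scales, _WAVELET, method="fft")
    return coefs


def _smooth(power: np.ndarray, scales_samples: np.ndarray) -> np.ndarray:
    """Morlet-matched smoothing: Gaussian in time (width ~ scale), boxcar
    over 3 adjacent scales."""
    out = np.empty_like(power)
    for i, s in enumerate(scales_samples):
        out[i] = ndimage.gaussian_filter1d(power[i], sigma=max(s, 1e-6), mode="nearest")
    if out.shape[0] >= 3:
        out = ndimage.uniform_filter1d(out, size=3, axis=0, mode="nearest")
    return out


def cross_wavelet(
    pair: MergedPair,
    band: tuple[float, float] = DEFAULT_BAND,
    scales_per_octave: int = SCALES_PER_OCTAVE,
) -> CrossWaveletResult:
    """Wavelet coherence and phase of a merged pair over the band.

    The window should contain at least two cycles of the lowest band
    frequency; if it does not, the low end of the band is truncated to the
    longest resolvable period (with a warning).
    """
    import warnings

    f0, f1 = band
    duration = pair.times[-1] - pair.times[0]
    min_f = 2.0 / duration if duration > 0 else f0
    if min_f > f0:
        warnings.warn(
            f"window of {duration:.2f} s too short for {f0} Hz; "
            f"band truncated to [{min_f:.2f}, {f1}] Hz",
            stacklevel=2,
        )
        f0 = min_f
        if f0 >= f1:
            raise ValueError("window too short for any band frequency")
    freqs = band_frequencies((f0, f1), scales_per_octave)
    Ws = _cwt(pair.speech, pair.rate, freqs)
    Wg = _cwt(pair.gesture, pair.rate, freqs)
    return _coherence_from_transforms(Ws, Wg, pair, freqs, (f0, f1))


def _coherence_from_transforms(Ws, Wg, pair, freqs, band) -> CrossWaveletResult:
    scales_samples = _MORLET_FC * pair.rate / freqs
    cross = Ws * np.conj(Wg)
    s_cross_r = _smooth(cross.real, scales_samples)
    s_cross_i = _smooth(cross.imag, scales_samples)
    s_ss = _smooth(np.abs(Ws) ** 2, scales_samples)
    s_gg = _smooth(np.abs(Wg) ** 2, scales_samples)
    denom = s_ss * s_gg
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = (s_cross_r**2 + s_cross_i**2) / denom
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    phase = np.arctan2(s_cross_i, s_cross_r)
    return CrossWaveletResult(
        times=pair.times, freqs=freqs, coherence=coh, phase=phase, band=band
    )


# ---------------------------------------------------------------------------
# Surrogate significance
# ---------------------------------------------------------------------------


def _phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with the same amplitude spectrum but random phases."""
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n)


def _ar1_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-matched Gaussian surrogate (lag-1 autocorrelation preserved)."""
    x = x - x.mean()
    denom = float(np.dot(x[:-1], x[:-1]))
    phi = float(np.dot(x[:-1], x[1:]) / denom) if denom > 0 else 0.0
    phi = np.clip(phi, -0.999, 0.999)
    sigma = x.std() * np.sqrt(1 - phi**2)
    out = np.empty_like(x)
    out[0] = x.std() * rng.standard_normal()
    eps = sigma * rng.standard_normal(x.size)
    for i in range(1, x.size):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def significance_mask(
    pair: MergedPair,
    n_surrogates: int = N_SURROGATES,
    seed: int | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "phase",
    p_threshold: float = P_THRESHOLD,
) -> tuple[CrossWaveletResult, np.ndarray, np.ndarray]:
    """Cell-wise coherence significance against a surrogate null.

    The null re-runs the cross-wavelet with the speech stream replaced by
    a surrogate (``"phase"``-randomised, or ``"ar1"``-matched noise),
    keeping the gesture stream fixed.  Cell p-values use the standard
    ``(1 + #{surrogate >= observed}) / (n + 1)`` estimator.  Returns the
    observed result, the boolean ``p < p_threshold`` mask, and the p-map.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a p < 0.05 test")
    rng = np.random.default_rng(seed)
    make = {"phase": _phase_randomize, "ar1": _ar1_surrogate}[method]
    observed = cross_wavelet(pair, band)
    freqs = observed.freqs
    Wg = _cwt(pair.gesture, pair.rate, freqs)
    exceed = np.zeros_like(observed.coherence, dtype=np.int64)
    for _ in range(n_surrogates):
        surr = make(pair.speech, rng)
        sd = surr.std()
        surr = (surr - surr.mean()) / (sd if sd > 1e-12 else 1.0)
        Ws = _cwt(surr, pair.rate, freqs)
        res = _coherence_from_transforms(Ws, Wg, pair, freqs, observed.band)
        exceed += res.coherence >= observed.coherence
    pmap = (1.0 + exceed) / (n_surrogates + 1.0)
    return observed, pmap < p_threshold, pmap


def summarize_alignment(
    result: CrossWaveletResult,
    mask: np.ndarray,
    event_ref: str = "",
    p_threshold: float = P_THRESHOLD,
) -> CoherenceResult | None:
    """Summarise reliable cells into one coherence + asynchrony value.

    Mean coherence over significant cells; phase is aggregated by circular
    mean per frequency row, converted to ms at that row's frequency
    (``dt = phi / (2 pi f)``), then combined across rows weighted by cell
    count.  Positive asynchrony means speech leads gesture.  An empty mask
    yields ``None`` — the event contributes no row downstream.
    """
    if mask.shape != result.coherence.shape:
        raise ValueError("mask shape does not match the coherence map")
    n_cells = int(mask.sum())
    if n_cells == 0:
        return None
    coh = float(result.coherence[mask].mean())
    lags_ms = []
    weights = []
    for i, f in enumerate(result.freqs):
        row = mask[i]
        if not row.any():
            continue
        ph = result.phase[i][row]
        mean_phase = np.arctan2(np.sin(ph).mean(), np.cos(ph).mean())
        lags_ms.append(1000.0 * mean_phase / (2.0 * np.pi * f))
        weights.append(row.sum())
    lag = float(np.average(lags_ms, weights=weights))
    return CoherenceResult(
        event_ref=event_ref,
        band=result.band,
        coherence=coh,
        phase_asynchrony_ms=lag,
        n_significant_cells=n_cells,
        p_threshold=p_threshold,
    )


def align_event(
    speech: tuple[np.ndarray, np.ndarray],
    gesture: tuple[np.ndarray, np.ndarray],
    event_ref: str = "",
    n_surrogates: int = N_SURROGATES,
    seed: int | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> CoherenceResult | None:
    """Full per-event alignment: merge, transform, test, summarise."""
    pair = merge_streams(speech, gesture)
    observed, mask, _ = significance_mask(
        pair, n_surrogates=n_surrogates, seed=seed, band=band
    )
    return summarize_alignment(observed, mask, event_ref)
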