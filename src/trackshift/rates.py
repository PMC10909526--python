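"""Acoustic rate estimation: envelopes, modulation spectra, syllable rate.

Two stimulus rates drive the tracking-shift analysis. The *modulation rate*
is the frequency of the global maximum of the stimulus modulation spectrum
(narrowband envelopes through a cochlear filterbank, spectra per 6-s segment,
root-mean-square across bands, averaged over segments). The *syllable rate*
counts intensity peaks (syllable nuclei) that stand out from surrounding dips,
per second of audio.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synthgen import Envelope
from .vocoder import band_edges

__all__ = [
    "extract_envelope",
    "modulation_spectrum",
    "center_frequency",
    "syllable_rate",
]


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _resample(x: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    if target_rate == rate:
        return x
    frac = Fraction(target_rate / rate).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def extract_envelope(
    audio: np.ndarray,
    rate: float,
    target_rate: float = 100.0,
    lowpass: float = 25.0,
    stimulus_id: str = "stim",
    condition: str = "",
) -> Envelope:
    """Broadband amplitude envelope: |analytic signal|, low-passed, resampled.

    The magnitude of the Hilbert analytic signal is low-pass filtered at
    ``lowpass`` Hz (zero-phase Butterworth), resampled to ``target_rate``
    and clipped at zero.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a nonempty 1-D array")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio must be finite")
    if target_rate > rate:
        raise ValueError("target_rate must not exceed the audio rate")
    env = np.abs(sps.hilbert(audio))
    if lowpass < rate / 2:
        env = _lowpass(env, rate, lowpass)
    env = _resample(env, rate, target_rate)
    return Envelope(
        samples=np.maximum(env, 0.0),
        rate=target_rate,
        stimulus_id=stimulus_id,
        condition=condition,
    )


def modulation_spectrum(
    audio: np.ndarray,
    rate: float,
    seg_len: float = 6.0,
    fmax: float = 25.0,
    n_bands: int = 32,
    f_lo: float = 200.0,
    f_hi: float = 7000.0,
    use_filterbank: "bool | None" = None,
):
    """Normalized modulation spectrum averaged over ``seg_len`` segments.

    For full-bandwidth audio (rate >= 2*f_hi) the signal is decomposed into
    ``n_bands`` cochlear (Greenwood-spaced) bands, each band's envelope is the
    magnitude of its analytic signal, and per segment the root-mean-square of
    the per-band envelope spectra (DC removed) forms the segment spectrum.
    A low-rate input (e.g. an already-extracted envelope) skips the filterbank
    and is analyzed directly. Segment spectra are averaged and the average is
    normalized to unit maximum.

    Returns ``(freqs, spectrum, n_segments)`` with frequency resolution
    ``1/seg_len`` Hz up to ``fmax``.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a nonempty 1-D array")
    n_seg_samp = int(round(seg_len * rate))
    if audio.size < n_seg_samp:
        raise ValueError(f"audio shorter than one {seg_len}-s segment")
    if use_filterbank is None:
        use_filterbank = rate >= 2 * f_hi

    env_rate = 100.0 if rate > 100.0 else rate
    if use_filterbank:
        edges = band_edges(n_bands, f_lo, f_hi)
        envs = []
        for b in range(n_bands):
            sos = sps.butter(4, [edges[b], edges[b + 1]], btype="bandpass", fs=rate, output="sos")
            band = sps.sosfiltfilt(sos, audio)
            env = np.abs(sps.hilbert(band))
            env = _lowpass(env, rate, fmax)
            envs.append(_resample(env, rate, env_rate))
        envs = np.asarray(envs)  # (bands, samples)
    else:
        envs = _resample(audio, rate, env_rate)[None, :]

    n_seg_samp = int(round(seg_len * env_rate))
    n_segments = envs.shape[1] // n_seg_samp
    if n_segments < 1:
        raise ValueError("audio shorter than one segment after resampling")
    freqs = np.fft.rfftfreq(n_seg_samp, d=1.0 / env_rate)
    keep = freqs <= fmax
    seg_spectra = np.zeros((n_segments, int(keep.sum())))
    for s in range(n_segments):
        seg = envs[:, s * n_seg_samp : (s + 1) * n_seg_samp]
        seg = seg - seg.mean(axis=1, keepdims=True)
        mag = np.abs(np.fft.rfft(seg, axis=1))[:, keep]
        seg_spectra[s] = np.sqrt(np.mean(mag**2, axis=0))  # RMS across bands
    spectrum = seg_spectra.mean(axis=0)
    peak = spectrum.max()
    if peak > 0:
        spectrum = spectrum / peak
    return freqs[keep], spectrum, n_segments


def center_frequency(freqs: np.ndarray, spectrum: np.ndarray, band: tuple[float, float]) -> float:
    """Frequency of the global maximum of ``spectrum`` within ``band`` (inclusive).

    Ties resolve to the lower frequency. If the maximum sits on a band edge
    (monotone spectrum in the band) the edge frequency is returned with a
    warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no grid point")
    f_band = freqs[mask]
    s_band = spectrum[mask]
    i = int(np.argmax(s_band))  # argmax returns the first (lowest-f) maximum
    if i == 0 or i == f_band.size - 1:
        warnings.warn(
            f"spectrum maximum lies on the band edge at {f_band[i]:.3g} Hz",
            stacklevel=2,
        )
    return float(f_band[i])


def syllable_rate(
    audio: np.ndarray,
    rate: float,
    silence_db: float = -25.0,
    min_dip_db: float = 2.0,
    frame_len: float = 0.032,
    hop: float = 0.010,
    voiced_only: bool = False,
) -> float:
    """Syllable nuclei per second from the intensity-peak algorithm.

    The intensity contour (frame RMS in dB relative to the loudest frame) is
    scanned for local maxima above ``silence_db``; a candidate peak is kept
    only if the intensity dips by at least ``min_dip_db`` dB between it and
    the previous accepted peak. With ``voiced_only=True`` peaks whose frame
    lacks periodicity in the 75-500 Hz pitch range (autocorrelation peak
    < 0.3) are discarded. Thresholds are relative, so the estimate is
    invariant to global gain. Silent audio returns 0 with a warning.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size < int(2 * rate):
        raise ValueError("audio must be at least 2 s long")
    n_frame = max(int(round(frame_len * rate)), 8)
    n_hop = max(int(round(hop * rate)), 1)
    n_frames = 1 + (audio.size - n_frame) // n_hop
    if n_frames < 3:
        raise ValueError("audio too short for an intensity contour")
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = audio[idx]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak_rms = rms.max()
    if peak_rms <= 0:
        warnings.warn("silent audio: syllable rate set to 0", stacklevel=2)
        return 0.0
    intensity = 20.0 * np.log10(np.maximum(rms / peak_rms, 1e-12))

    cand, _ = sps.find_peaks(intensity, height=silence_db)
    accepted: list[int] = []
    for c in cand:
        if not accepted:
            accepted.append(c)
            continue
        valley = intensity[accepted[-1] : c + 1].min()
        if intensity[c] - valley >= min_dip_db:
            accepted.append(c)
        elif intensity[c] > intensity[accepted[-1]]:
            accepted[-1] = c  # same nucleus, keep the louder frame

    if voiced_only and accepted:
        lag_lo = int(rate / 500.0)
        lag_hi = int(rate / 75.0)
        kept = []
        for c in accepted:
            fr = frames[c] - frames[c].mean()
            denom = np.sum(fr**2)
            if denom <= 0 or lag_hi >= fr.size:
                continue
            ac = np.correlate(fr, fr, mode="full")[fr.size - 1 :]
            ac = ac / denom
            if ac[lag_lo : lag_hi + 1].max() >= 0.3:
                kept.append(c)
        accepted = kept

    duration = audio.size / rate
    return len(accepted) / duration
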