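"""Power-law (1/f^beta) noise synthesis via spectral shaping of white noise."""

from __future__ import annotations

import numpy as np


def powerlaw_noise(
    n: int,
    exponent: float,
    rng: np.random.Generator,
    rate: float = 1.0,
    shoulder: "float | None" = None,
) -> np.ndarray:
    """Generate ``n`` samples of Gaussian noise with power spectrum ~ 1/f**exponent.

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to ``f**(-exponent/2)``; the DC bin is zeroed. The output is
    rescaled to unit standard deviation (the caller sets the amplitude).

    Parameters
    ----------
    n : number of samples.
    exponent : spectral exponent beta (0 = white, 1 = pink, 2 = brown).
    rng : numpy Generator supplying the white noise.
    rate : sampling rate in Hz; only sets the physical frequency scale and is
        irrelevant for a pure power law, kept for clarity.
    shoulder : optional corner frequency (Hz) of a second-order low-frequency
        shoulder ``f^2 / (f^2 + shoulder^2)`` applied to the amplitude
        response; the spectrum then rises to a broad maximum above the corner
        and falls as the power law beyond it (the shape of speech modulation
        spectra, which roll off below a few Hz instead of diverging).
    """
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    white = rng.standard_normal(n)
    if exponent == 0 and shoulder is None:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    if shoulder is not None:
        shape[1:] *= f[1:] ** 2 / (f[1:] ** 2 + shoulder**2)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def narrowband_noise(
    n: int,
    center: float,
    bandwidth: float,
    rng: np.random.Generator,
    rate: float,
) -> np.ndarray:
    """Gaussian noise with a Gaussian spectral bump at ``center`` Hz.

    The amplitude response is exp(-(f-center)^2 / (2 sigma^2)) with
    sigma = bandwidth / 2, so ``bandwidth`` is roughly the 2-SD spectral width.
    Output has unit standard deviation.
    """
    if not (0 < center < rate / 2):
        raise ValueError(f"center must lie in (0, rate/2); got {center}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    sigma = bandwidth / 2.0
    shape = np.exp(-((f - center) ** 2) / (2.0 * sigma**2))
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x
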