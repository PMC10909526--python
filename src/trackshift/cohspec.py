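"""Epoching, epoch-count equalization and multitaper envelope-brain coherence.

Coherence between the stimulus envelope and each neural channel is estimated
with DPSS (multitaper) spectra on 4-s epochs: cross- and auto-spectra are
pooled over epochs and tapers, and magnitude coherence is

    C(f) = |sum_{e,k} X_ek(f) Y_ek(f)*| / sqrt(sum |X|^2 * sum |Y|^2)

on a regular 0-25 Hz grid in 0.25 Hz steps with +/-4 Hz spectral smoothing
(K = 2*T*W - 1 = 31 tapers for T = 4 s). Epoch counts are equalized across
conditions by seeded random subselection to the minimum count, so estimator
bias (which depends on the number of averaged segments) is comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .synthgen import EpochSet, Envelope

__all__ = [
    "CoherenceSpectrum",
    "epoch_signal",
    "epoch_and_equalize",
    "equalize_epochsets",
    "mtm_coherence",
    "band_average",
    "highpass_continuous",
]


@dataclass
class CoherenceSpectrum:
    """Per-channel envelope-brain coherence on a regular frequency grid."""

    freqs: np.ndarray  # (n_freqs,) Hz
    coh: np.ndarray  # (n_channels, n_freqs), values in [0, 1]
    n_epochs: int
    n_tapers: int
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.coh = np.atleast_2d(np.asarray(self.coh, dtype=float))
        if self.coh.shape[1] != self.freqs.size:
            raise ValueError("coh and freqs shapes disagree")
        if np.any(self.coh < -1e-12) or np.any(self.coh > 1 + 1e-9):
            raise ValueError("coherence values outside [0, 1]")


def epoch_signal(x: np.ndarray, rate: float, epoch_len: float) -> np.ndarray:
    """Cut a 1-D signal into consecutive ``epoch_len`` windows (remainder dropped)."""
    x = np.asarray(x, dtype=float)
    n = int(round(epoch_len * rate))
    n_epochs = x.size // n
    if n_epochs < 1:
        raise ValueError("signal shorter than one epoch")
    return x[: n_epochs * n].reshape(n_epochs, n)


def epoch_and_equalize(
    continuous: "dict[str, tuple[np.ndarray, np.ndarray]]",
    rate: float,
    epoch_len: float = 4.0,
    seed: int = 0,
) -> "dict[str, tuple[EpochSet, np.ndarray]]":
    """Epoch per-condition continuous data and equalize epoch counts.

    ``continuous`` maps condition -> (neural array of shape (channels,
    samples), envelope samples). Each condition is cut into half-open
    ``epoch_len`` windows; all conditions are then reduced to the minimum
    epoch count by seeded random subselection (the same epochs are kept for
    the neural data and the envelope).
    """
    epoched: dict[str, tuple[EpochSet, np.ndarray]] = {}
    for cond, (neural, env) in continuous.items():
        neural = np.atleast_2d(np.asarray(neural, dtype=float))
        n = int(round(epoch_len * rate))
        n_epochs = neural.shape[1] // n
        if n_epochs < 1:
            raise ValueError(f"condition {cond!r} has 0 complete epochs")
        data = neural[:, : n_epochs * n].reshape(neural.shape[0], n_epochs, n)
        es = EpochSet(
            data=np.transpose(data, (1, 0, 2)),
            rate=rate,
            epoch_len=epoch_len,
            condition=cond,
        )
        env_ep = epoch_signal(np.asarray(env, dtype=float), rate, epoch_len)
        if env_ep.shape[0] < n_epochs:
            raise ValueError(f"envelope shorter than neural data for {cond!r}")
        epoched[cond] = (es, env_ep[:n_epochs])
    return equalize_epochsets(epoched, seed=seed)


def equalize_epochsets(
    epoched: "dict[str, tuple[EpochSet, np.ndarray]]",
    seed: int = 0,
) -> "dict[str, tuple[EpochSet, np.ndarray]]":
    """Reduce every condition to the minimum epoch count by seeded subselection."""
    if not epoched:
        raise ValueError("no conditions given")
    n_min = min(es.n_epochs for es, _ in epoched.values())
    if n_min < 1:
        raise ValueError("a condition has 0 epochs")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[EpochSet, np.ndarray]] = {}
    for cond, (es, env_ep) in epoched.items():
        if es.n_epochs == n_min:
            out[cond] = (es, env_ep)
            continue
        keep = np.sort(rng.choice(es.n_epochs, size=n_min, replace=False))
        out[cond] = (
            EpochSet(
                data=es.data[keep],
                rate=es.rate,
                epoch_len=es.epoch_len,
                condition=es.condition,
                subject_id=es.subject_id,
            ),
            env_ep[keep],
        )
    return out


def mtm_coherence(
    epochs: EpochSet,
    env_epochs: np.ndarray,
    fmax: float = 25.0,
    step: float = 0.25,
    smoothing: float = 4.0,
    eig_cutoff: float = 0.9,
    squared: bool = False,
) -> CoherenceSpectrum:
    """Multitaper coherence between every channel and the epoched envelope.

    DPSS tapers with time-bandwidth NW = epoch_len * smoothing are applied to
    each epoch; K = 2*NW - 1 tapers are requested and those with energy
    concentration below ``eig_cutoff`` are discarded. Cross- and auto-spectra
    are summed over epochs and tapers before forming magnitude coherence
    (``squared=True`` returns the squared variant). The grid runs from 0 to
    ``fmax`` in ``step`` Hz increments; epochs shorter than 1/step seconds are
    zero-padded to that length.
    """
    env_epochs = np.atleast_2d(np.asarray(env_epochs, dtype=float))
    if env_epochs.shape != (epochs.n_epochs, epochs.data.shape[2]):
        raise ValueError("env_epochs must match the EpochSet (n_epochs, n_samples)")
    rate = epochs.rate
    n_samp = epochs.data.shape[2]
    nw = epochs.epoch_len * smoothing
    if smoothing >= fmax:
        raise ValueError("smoothing must be below fmax")
    k_req = max(int(round(2 * nw - 1)), 1)
    tapers, ratios = windows.dpss(n_samp, nw, Kmax=k_req, return_ratios=True)
    keep = ratios > eig_cutoff
    if not np.any(keep):
        keep = ratios >= ratios.max()
    tapers = tapers[keep]
    n_tapers = tapers.shape[0]
    if epochs.n_epochs * n_tapers < 2:
        raise ValueError(
            "degenerate coherence estimate: a single epoch-taper segment is "
            "identically 1; need epochs x tapers >= 2"
        )

    nfft = int(round(rate / step))
    if nfft < n_samp:
        raise ValueError(
            f"step {step} Hz needs nfft {nfft} < epoch length {n_samp}; "
            "use a finer step or shorter epochs"
        )
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    sel = freqs <= fmax + 1e-9
    freqs = freqs[sel]

    # per-epoch demeaning: a DC line would otherwise leak into every
    # auto-spectrum within the +/-smoothing window of 0 Hz
    env_d = env_epochs - env_epochs.mean(axis=1, keepdims=True)
    dat_d = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    # tapered FFTs: env (epochs, tapers, freqs); neural (epochs, ch, tapers, freqs)
    env_t = np.fft.rfft(env_d[:, None, :] * tapers[None, :, :], n=nfft, axis=-1)[..., sel]
    dat_t = np.fft.rfft(
        dat_d[:, :, None, :] * tapers[None, None, :, :], n=nfft, axis=-1
    )[..., sel]

    sxy = np.sum(dat_t * np.conj(env_t[:, None, :, :]), axis=(0, 2))
    sxx = np.sum(np.abs(dat_t) ** 2, axis=(0, 2))
    syy = np.sum(np.abs(env_t) ** 2, axis=(0, 1))
    denom = np.sqrt(sxx * syy[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    if squared:
        coh = coh**2
    return CoherenceSpectrum(
        freqs=freqs,
        coh=coh,
        n_epochs=epochs.n_epochs,
        n_tapers=n_tapers,
        condition=epochs.condition,
        subject_id=epochs.subject_id,
    )


def band_average(cs: CoherenceSpectrum, band: tuple[float, float] = (2.0, 7.0)) -> np.ndarray:
    """Per-channel mean coherence over grid points with band[0] <= f <= band[1]."""
    mask = (cs.freqs >= band[0] - 1e-9) & (cs.freqs <= band[1] + 1e-9)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no grid point")
    return cs.coh[:, mask].mean(axis=1)


def highpass_continuous(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR high-pass of continuous data (last axis is time).

    A windowed-sinc (Hamming) FIR with a transition band of about half the
    cutoff is applied forward-backward. Mirrors the optional 0.1 Hz / 1 Hz
    preprocessing whose choice is known to alter aperiodic components.
    """
    from scipy import signal as sps

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    numtaps = int(6 * rate / cutoff) | 1  # odd
    x = np.asarray(x, dtype=float)
    numtaps = min(numtaps, 2 * (x.shape[-1] // 3) - 1)
    b = sps.firwin(numtaps, cutoff, pass_zero=False, fs=rate)
    return sps.filtfilt(b, [1.0], x, axis=-1, padtype="even")
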