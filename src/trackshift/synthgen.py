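"""Synthetic cohorts of speech-like envelopes and envelope-tracking neural signals.

This module generates every input the analysis pipeline consumes: amplitude
envelopes with a 1/f-shaped modulation spectrum peaking at a controllable
rate, multichannel "virtual channel" time series that track the envelope in a
narrow frequency band on top of power-law background noise, syllable-like
burst audio with a known burst rate, and binomial behavior tables for a
two-alternative task. A cohort couples these pieces across subjects and
conditions so that the tracking center frequency, coupling strength and noise
background can be moved independently — the knobs the downstream statistics
are meant to detect.

Randomness is derived from a single integer seed expanded into independent
substreams per subject x condition via :class:`numpy.random.SeedSequence`
spawn keys, so any subset of a cohort is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._noise import narrowband_noise, powerlaw_noise

__all__ = [
    "Envelope",
    "EpochSet",
    "BurstAudio",
    "ConditionSpec",
    "CohortSpec",
    "SubjectRecording",
    "gen_envelope",
    "gen_neural_epochs",
    "gen_cohort",
    "gen_burst_audio",
    "gen_multiband_audio",
    "gen_behavior",
    "write_cohort",
]


@dataclass
class Envelope:
    """Nonnegative amplitude envelope of one stimulus."""

    samples: np.ndarray
    rate: float
    stimulus_id: str = "stim"
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("envelope samples must be a nonempty 1-D array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be nonnegative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class EpochSet:
    """Epochs x channels x samples of (modeled) neural activity."""

    data: np.ndarray
    rate: float
    epoch_len: float
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (epochs, channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet.data must be finite")
        expected = int(round(self.epoch_len * self.rate))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length mismatch: {self.data.shape[2]} samples != "
                f"round(epoch_len * rate) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class BurstAudio:
    """Waveform with periodic amplitude bursts plus its ground-truth gate."""

    samples: np.ndarray
    rate: float
    gate: np.ndarray
    burst_rate: float


@dataclass
class ConditionSpec:
    """Generative parameters for one vocoding-like condition.

    ``coupling_snr`` scales the narrowband (periodic) envelope tracking at
    ``tracking_cf``; ``aperiodic_snr`` scales the broadband shared slow drive
    that produces the 1/f-like aperiodic component of envelope-brain
    coherence. Lowering ``aperiodic_snr`` across conditions emulates a drop
    in overall coupling (band coherence, aperiodic offset) without touching
    the periodic peak height.
    """

    name: str
    tracking_cf: float  # Hz, center of the envelope-to-brain coupling band
    tracking_bw: float = 1.0  # Hz, width of the coupling band
    coupling_snr: float = 0.3  # power ratio of periodic tracking vs background
    aperiodic_snr: float = 0.3  # power ratio of shared slow drive vs background
    broadband_snr: float = 0.08  # power ratio of shared broadband comodulation
    noise_exponent: float = 1.0  # power-law beta of the neural background
    env_mod_rate: float = 4.5  # Hz, peak of the stimulus modulation spectrum
    env_mod_bw: float = 2.0  # Hz, spectral width of that peak
    env_mod_depth: float = 0.8  # amplitude of the modulation peak
    env_exponent: float = 1.0  # power-law beta of the envelope floor


@dataclass
class CohortSpec:
    """Full design of a synthetic study cohort.

    ``cf_jitter_sd`` (Hz) and ``log_snr_jitter_sd`` (natural-log units) are
    the between-subject SDs applied to each condition's tracking center
    frequency and coupling SNR; they create realistic within/between-subject
    variance for the repeated-measures statistics.
    """

    n_subjects: int
    conditions: list[ConditionSpec]
    n_epochs: int = 60
    epoch_len: float = 4.0
    n_channels: int = 4
    rate: float = 100.0
    seed: int = 0
    cf_jitter_sd: float = 0.2
    log_snr_jitter_sd: float = 0.2
    env_slow_amp: float = 0.8  # amplitude of the shared slow (prosodic) drive
    env_floor_shoulder: float = 2.5  # Hz, low-frequency shoulder of the envelope floor
    noise_shoulder: "float | None" = 1.5  # Hz, shoulder of the neural background
    env_broadband_amp: float = 0.4  # amplitude of shared broadband comodulation in the envelope

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_epochs < 2:
            raise ValueError("n_epochs must be >= 2")
        for c in self.conditions:
            if not (0 < c.tracking_cf < self.rate / 2):
                raise ValueError(
                    f"tracking_cf {c.tracking_cf} outside (0, rate/2) for {c.name}"
                )
            if c.coupling_snr < 0:
                raise ValueError("coupling_snr must be >= 0")


@dataclass
class SubjectRecording:
    """One subject x condition cell: epoched neural data + its stimulus envelope."""

    subject_id: str
    condition: str
    epochs: EpochSet
    envelope: Envelope
    true_cf: float = float("nan")
    true_snr: float = float("nan")


def _subject_rng(seed: int, subject: int, condition: int) -> np.random.Generator:
    # counter-based substream: (seed; subject, condition) -> independent stream
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject, condition))
    )


def gen_envelope(
    rate: float,
    duration: float,
    mod_rate: float,
    mod_bw: float = 0.5,
    exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    mod_depth: float = 1.0,
    extra_peak: "tuple[float, float, float] | None" = None,
    extra_component: "np.ndarray | None" = None,
    floor_shoulder: "float | None" = 2.5,
    stimulus_id: str = "stim",
    condition: str = "",
) -> Envelope:
    """Speech-like amplitude envelope with a controllable modulation peak.

    The envelope is a rectified sum of a unit-variance power-law noise floor
    (spectrum ~ 1/f**exponent), a narrowband Gaussian-spectrum modulator
    centered at ``mod_rate`` with width ``mod_bw`` scaled by ``mod_depth``,
    and a constant baseline of 1 that keeps rectification mild. The result is
    nonnegative and its modulation spectrum peaks at ``mod_rate``; with
    ``mod_depth=0`` no peak is injected.

    ``extra_peak=(center, bandwidth, depth)`` adds a secondary, weaker
    narrowband component — envelope energy at the frequency a downstream
    neural channel tracks, analogous to syllable-band energy in real speech.
    Its depth should stay below ``mod_depth`` so the modulation spectrum's
    global maximum remains at ``mod_rate``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration < 12.0:
        raise ValueError("duration must be >= 12 s for stable rate estimates")
    if not (0 < mod_rate < rate / 2):
        raise ValueError(f"mod_rate must lie in (0, rate/2); got {mod_rate}")
    if mod_depth < 0:
        raise ValueError("mod_depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    # the floor is power-law above a ~2.5 Hz shoulder: speech modulation
    # spectra roll off below a few Hz rather than diverging like a pure 1/f
    floor = powerlaw_noise(n, exponent, rng, rate=rate, shoulder=floor_shoulder)
    x = floor + 1.0
    if mod_depth > 0:
        x = x + mod_depth * narrowband_noise(n, mod_rate, mod_bw, rng, rate=rate)
    if extra_component is not None:
        extra_component = np.asarray(extra_component, dtype=float)
        if extra_component.shape != x.shape:
            raise ValueError("extra_component must match the envelope length")
        x = x + extra_component
    elif extra_peak is not None:
        c, bw, depth = extra_peak
        x = x + depth * narrowband_noise(n, c, bw, rng, rate=rate)
    samples = np.maximum(x, 0.0)
    return Envelope(samples=samples, rate=rate, stimulus_id=stimulus_id, condition=condition)


def gen_neural_epochs(
    env: Envelope,
    n_channels: int,
    coupling_cf: float,
    coupling_bw: float = 1.0,
    snr: float = 1.0,
    noise_exponent: float = 1.0,
    epoch_len: float = 4.0,
    seed: int | np.random.Generator = 0,
    coupled_source: "np.ndarray | None" = None,
    aperiodic_snr: float = 0.0,
    aperiodic_source: "np.ndarray | None" = None,
    noise_shoulder: "float | None" = 1.5,
    shared_extra: "np.ndarray | None" = None,
    condition: str = "",
    subject_id: str = "",
) -> EpochSet:
    """Multichannel neural activity that tracks ``env`` in a narrow band.

    Each channel is ``sqrt(snr) * coupled + sqrt(aperiodic_snr) * slow +
    powerlaw_noise``. ``coupled`` is the envelope band-pass filtered to
    ``coupling_cf +/- coupling_bw/2`` (4th-order Butterworth, zero phase) —
    or, when ``coupled_source`` is given, that explicit component of the
    envelope (e.g. the tracking component a cohort injected). ``slow``
    (``aperiodic_source``, optional) is a broadband component shared with the
    envelope that produces the 1/f-like aperiodic part of the coherence
    spectrum. All components are scaled to unit variance, so the snr values
    are power ratios against the background noise. The continuous signal is
    cut into consecutive ``epoch_len`` windows, dropping the remainder.
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    lo = coupling_cf - coupling_bw / 2.0
    hi = coupling_cf + coupling_bw / 2.0
    if not (0 < lo < hi < env.rate / 2):
        raise ValueError(
            f"coupling band [{lo}, {hi}] Hz outside (0, rate/2) = (0, {env.rate / 2})"
        )
    n = env.samples.size
    samp_per_epoch = int(round(epoch_len * env.rate))
    n_epochs = n // samp_per_epoch
    if n_epochs < 2:
        raise ValueError("envelope too short for >= 2 epochs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if snr > 0:
        if coupled_source is not None:
            coupled = np.asarray(coupled_source, dtype=float).copy()
            if coupled.size != n:
                raise ValueError("coupled_source must match the envelope length")
        else:
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=env.rate, output="sos")
            coupled = sps.sosfiltfilt(sos, env.samples - env.samples.mean())
        sd = coupled.std()
        if sd > 0:
            coupled = coupled / sd
        coupled = np.sqrt(snr) * coupled
    else:
        coupled = np.zeros(n)
    if aperiodic_snr < 0:
        raise ValueError("aperiodic_snr must be >= 0")
    if aperiodic_snr > 0 and aperiodic_source is not None:
        slow = np.asarray(aperiodic_source, dtype=float)
        if slow.size != n:
            raise ValueError("aperiodic_source must match the envelope length")
        sd = slow.std()
        coupled = coupled + np.sqrt(aperiodic_snr) * (slow / sd if sd > 0 else slow)
    if shared_extra is not None:
        # pre-scaled shared component (e.g. broadband comodulation)
        coupled = coupled + np.asarray(shared_extra, dtype=float)

    # the noise shoulder emulates high-pass-filtered recordings: measured
    # neural data are high-passed (0.1-1 Hz), so the background power law
    # flattens below ~1.5 Hz instead of diverging
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        data[ch] = coupled + powerlaw_noise(
            n, noise_exponent, rng, rate=env.rate, shoulder=noise_shoulder
        )
    used = n_epochs * samp_per_epoch
    epochs = data[:, :used].reshape(n_channels, n_epochs, samp_per_epoch)
    epochs = np.transpose(epochs, (1, 0, 2))
    return EpochSet(
        data=epochs,
        rate=env.rate,
        epoch_len=epoch_len,
        condition=condition,
        subject_id=subject_id,
    )


def gen_cohort(spec: CohortSpec) -> list[SubjectRecording]:
    """Generate a full subject cohort from a :class:`CohortSpec`.

    Per subject and condition, the tracking center frequency is jittered by a
    Gaussian with SD ``spec.cf_jitter_sd`` Hz and the coupling SNR by a
    log-normal with log-SD ``spec.log_snr_jitter_sd``; every cell gets its own
    stimulus envelope and noise realization from an independent substream.
    """
    records: list[SubjectRecording] = []
    duration = spec.n_epochs * spec.epoch_len
    for s in range(spec.n_subjects):
        sid = f"sub-{s + 1:02d}"
        for ci, cond in enumerate(spec.conditions):
            rng = _subject_rng(spec.seed, s, ci)
            cf = cond.tracking_cf + spec.cf_jitter_sd * rng.standard_normal()
            # keep the jittered CF inside the analyzable band
            cf = float(np.clip(cf, 0.5, spec.rate / 2 - 1.0))
            jitter = np.exp(spec.log_snr_jitter_sd * rng.standard_normal())
            snr = cond.coupling_snr * jitter if cond.coupling_snr > 0 else 0.0
            ap_snr = cond.aperiodic_snr * jitter if cond.aperiodic_snr > 0 else 0.0
            # the envelope carries (a) an explicit tracking component at the
            # jittered coupling CF — the envelope energy the neural channels
            # lock to, analogous to syllable-band energy in real speech —
            # weaker (amplitude 0.5) than the modulation peak so the
            # modulation spectrum's global maximum stays at env_mod_rate, and
            # (b) a slow (beta = 2) prosodic-scale drive shared with the
            # channels that yields the 1/f-like aperiodic coherence component
            # a weak shared broadband comodulation raises the coherence floor
            # to a realistic level (real recordings share global gain
            # fluctuations), keeping the peak-to-floor contrast in the regime
            # the spectral parametrization is built for
            n_samp = int(round(duration * spec.rate))
            tracking = narrowband_noise(n_samp, cf, cond.tracking_bw, rng, rate=spec.rate)
            slow = powerlaw_noise(n_samp, 2.0, rng, rate=spec.rate)
            broadband = rng.standard_normal(n_samp)
            env = gen_envelope(
                rate=spec.rate,
                duration=duration,
                mod_rate=cond.env_mod_rate,
                mod_bw=cond.env_mod_bw,
                exponent=cond.env_exponent,
                seed=rng,
                mod_depth=cond.env_mod_depth,
                extra_component=0.5 * tracking + spec.env_slow_amp * slow
                + spec.env_broadband_amp * broadband,
                floor_shoulder=spec.env_floor_shoulder,
                stimulus_id=f"{sid}_{cond.name}",
                condition=cond.name,
            )
            epochs = gen_neural_epochs(
                env,
                n_channels=spec.n_channels,
                coupling_cf=cf,
                coupling_bw=cond.tracking_bw,
                snr=snr,
                noise_exponent=cond.noise_exponent,
                epoch_len=spec.epoch_len,
                seed=rng,
                coupled_source=tracking,
                aperiodic_snr=ap_snr,
                aperiodic_source=slow,
                noise_shoulder=spec.noise_shoulder,
                shared_extra=np.sqrt(cond.broadband_snr * jitter) * broadband
                if cond.broadband_snr > 0 else None,
                condition=cond.name,
                subject_id=sid,
            )
            records.append(
                SubjectRecording(
                    subject_id=sid,
                    condition=cond.name,
                    epochs=epochs,
                    envelope=env,
                    true_cf=cf,
                    true_snr=float(snr),
                )
            )
    return records


def gen_burst_audio(
    rate: float,
    duration: float,
    burst_rate: float,
    carrier: str = "noise",
    seed: int | np.random.Generator = 0,
    duty: float = 0.5,
    floor_amp: float = 0.02,
) -> BurstAudio:
    """Audio with periodic syllable-like amplitude bursts.

    The gate is a train of Hann pulses of width ``duty / burst_rate`` at the
    burst period, sitting on a small floor (default 0.02, i.e. a ~34 dB
    inter-burst intensity dip) so the dip criterion of syllable-nuclei
    detection is unambiguous. The carrier is white noise or a harmonic
    complex on a 220 Hz fundamental.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (1.0 <= burst_rate <= 10.0):
        raise ValueError("burst_rate must lie in [1, 10] Hz")
    if carrier not in ("noise", "harmonic"):
        raise ValueError(f"unknown carrier {carrier!r}")
    min_rate = 2000.0 if carrier == "noise" else 2 * 220.0 * 8
    if rate < min_rate:
        raise ValueError(f"rate {rate} Hz too low for carrier {carrier!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    period = 1.0 / burst_rate
    width = duty * period
    gate = np.full(n, floor_amp)
    # center the first burst half a period in so partial bursts are not clipped
    centers = np.arange(period / 2.0, duration, period)
    half = width / 2.0
    for c in centers:
        i0 = max(int(np.ceil((c - half) * rate)), 0)
        i1 = min(int(np.floor((c + half) * rate)) + 1, n)
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - c) / width  # in [-0.5, 0.5]
        gate[i0:i1] = np.maximum(gate[i0:i1], np.cos(np.pi * phase) ** 2)

    if carrier == "noise":
        carr = rng.standard_normal(n)
    else:
        f0 = 220.0
        n_harm = int(min(8, (rate / 2 - 1) // f0))
        carr = np.zeros(n)
        for h in range(1, n_harm + 1):
            carr += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
    carr /= np.max(np.abs(carr))
    samples = gate * carr
    return BurstAudio(samples=samples, rate=rate, gate=gate, burst_rate=burst_rate)


def gen_multiband_audio(
    rate: float,
    duration: float,
    n_bands: int = 7,
    mod_rate: float = 3.0,
    mod_bw: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Audio with an independent slow random envelope in every cochlear band.

    Each of ``n_bands`` Greenwood-spaced bands (200-7000 Hz) carries band-pass
    noise modulated by its own nonnegative random envelope (narrowband noise
    around ``mod_rate``, width ``mod_bw``, rectified about a unit baseline).
    Because the band envelopes are mutually independent, coarse vocoding
    mixes them — the fixture that makes channel-count effects on envelope
    preservation visible, unlike a common broadband gate.
    """
    from scipy import signal as sps

    from .vocoder import band_edges

    if rate < 2 * 7000:
        raise ValueError("rate must be at least 14 kHz for the 200-7000 Hz bands")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    edges = band_edges(n_bands)
    audio = np.zeros(n)
    for i in range(n_bands):
        sos = sps.butter(4, [edges[i], edges[i + 1]], btype="bandpass", fs=rate, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        env = np.maximum(narrowband_noise(n, mod_rate, mod_bw, rng, rate=rate) + 1.0, 0.0)
        audio += env * carrier / carrier.std()
    return audio


def gen_behavior(
    n_subjects: int,
    hit_prob: "list[float] | dict[str, float]",
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial hit counts for a two-alternative task, per subject x condition.

    Returns a long table (subject, condition, hits, n_trials, hit_rate).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(hit_prob, dict):
        items = list(hit_prob.items())
    else:
        items = [(f"cond-{i + 1}", p) for i, p in enumerate(hit_prob)]
    for name, p in items:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"hit probability for {name} outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for name, p in items:
            hits = int(rng.binomial(n_trials, p))
            rows.append(
                {
                    "subject": f"sub-{s + 1:02d}",
                    "condition": name,
                    "hits": hits,
                    "n_trials": n_trials,
                    "hit_rate": hits / n_trials,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecording], spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a cohort as a directory tree with a manifest.

    Layout: ``<out>/<subject>/<condition>/epochs.npy`` (epochs x channels x
    samples) plus ``envelope.tsv`` (sample, amplitude), and a top-level
    ``manifest.json`` recording the CohortSpec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        d = out / rec.subject_id / rec.condition
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", rec.epochs.data)
        pd.DataFrame(
            {"sample": np.arange(rec.envelope.samples.size), "amplitude": rec.envelope.samples}
        ).to_csv(d / "envelope.tsv", sep="\t", index=False)
    manifest = asdict(spec)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
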