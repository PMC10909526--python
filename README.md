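# trackshift

Tools for asking *what* the brain tracks in speech, not just *how much*.

Low-frequency coherence between the speech amplitude envelope and neural
activity ("neural speech tracking") is usually summarized as a band average,
e.g. mean coherence over 2–7 Hz. But a coherence spectrum, like a power
spectrum, superimposes two different things: an aperiodic 1/f-like background
and periodic peaks riding on it. A band average conflates them — it can rise
or fall with broadband signal-to-noise changes that have nothing to do with
tracking at any particular rate. This package decomposes envelope–brain
coherence spectra into both parts and treats the **periodic peak's center
frequency (CF)** as the tracking index: across intelligibility conditions
(noise vocoding with fewer and fewer channels), the CF shifts away from the
syllable rate of the speech toward the acoustic modulation rate, while the
band average mostly reflects the aperiodic background.

Because the underlying recordings of such studies are not public, the package
ships a first-class synthetic-data module that generates speech-like
envelopes and envelope-tracking multichannel "virtual channel" signals with
controllable tracking CF, coupling SNR and background, so the entire analysis
chain is verifiable at desk scale.

## The model

Coherence between the epoched envelope `y` and each channel `x` is the
pooled-multitaper magnitude coherence on a 0–25 Hz grid (0.25 Hz steps),
with DPSS tapers (4-s epochs, ±W Hz smoothing, K = 2·T·W − 1 tapers):

```
C(f) = |Σ_{e,k} X_ek(f) Y*_ek(f)| / sqrt(Σ|X_ek(f)|² · Σ|Y_ek(f)|²)
```

Each coherence spectrum is then modeled in log₁₀ units as

```
log10 C(f) ≈ b − χ·log10 f  +  Σ_i a_i · exp(−(f − c_i)² / (2 w_i²))
```

an aperiodic line (offset `b`, exponent `χ`) plus Gaussian peaks (center
`c` in Hz, height `a` in log units above the line, width `w`; reported
bandwidth 2w). The most prominent peak with `c` in 2–7 Hz is the tracking
peak; peaks must exceed 1.5 SD of the flattened spectrum, and channels whose
fit quality deviates from the rest by more than 2.5 SD are dropped.

Downstream, per-subject CFs are compared against the stimulus **syllable
rate** (intensity-peak counting with a 2 dB dip criterion) and **modulation
rate** (global maximum of the cochlear-filterbank modulation spectrum on 6-s
segments) via |CF − rate| differences in a tracking × vocoding
repeated-measures ANOVA, and via an ensemble of k-nearest-neighbor
classifiers trained on labeled acoustic rates. The inference battery
(RM-ANOVAs with Greenhouse–Geisser correction, FDR post-hocs, Wilcoxon /
Mann–Whitney tests, cluster-based permutation, repeated-measures correlation,
dominance analysis) is implemented from first principles and verified against
brute-force oracles.

## A worked example

```sh
python examples/05_full_study.py
```

runs the bundled scaled study — 8 subjects × 3 conditions whose tracking CFs
(4.2, 4.8, 5.3 Hz) move from the 4 Hz syllable rate toward the 5.5 Hz
modulation rate while the overall coupling gain drops — and prints:

```
           band_coh     cf  height  offset
condition
original      0.305  3.796   0.911  -0.864
vocoded3      0.223  5.835   1.086  -1.167
vocoded7      0.263  4.565   1.052  -0.989

tracking x vocoding interaction: F = 33.9, p_gg = 0.0004
```

Reading it: band coherence and the aperiodic offset fall together as
vocoding degrades the stimulus (a gain effect), the peak height barely moves,
and the extracted CF climbs from near the syllable rate toward the modulation
rate — the interaction of |CF − syllable| (growing) with |CF − modulation|
(shrinking) is the headline tracking shift. A markdown report with all five
result sections lands in `study_results/report.md`. The other scripts in
`examples/` each demonstrate one capability (parametrization, vocoding, rate
estimation, the inference battery, the aperiodic simulations).

A thin CLI covers the shell-side chores:

```sh
trackshift vocode --in speech.wav --channels 3 --out speech_voc3.wav --seed 7
trackshift rates --in stimuli/ --out rates.tsv
trackshift run --config examples/study_config.yaml --out results/
```

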