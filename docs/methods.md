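# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Coherence estimation

Envelope–brain coherence is estimated per channel from 4-s epochs with DPSS
(multitaper) spectra. With epoch length T and half-bandwidth smoothing W the
time–bandwidth product is NW = T·W and K = 2·T·W − 1 tapers are requested;
tapers whose energy-concentration ratio falls below 0.9 are discarded
(K = 31 → 30 retained for T = 4 s, W = 4 Hz). Cross- and auto-spectra are
summed over epochs and tapers before the magnitude ratio is formed
(`squared=True` gives squared coherence). Epochs are demeaned individually —
without this the envelope's DC component leaks into every auto-spectrum
within ±W of 0 Hz and suppresses all low-frequency coherence. The frequency
grid runs 0–25 Hz in 0.25 Hz steps, the native Rayleigh resolution of a 4-s
epoch; shorter epochs are zero-padded to reach the grid. Identical inputs
give coherence exactly 1; independent inputs give the small-sample bias of a
magnitude coherence over n = epochs × tapers segments, ≈ sqrt(π/(4n)),
which the acceptance script verifies against a Monte-Carlo oracle.

Epoch counts are equalized across conditions by seeded random subselection to
the minimum count, so this bias is comparable across conditions.

### Smoothing and frequency resolution

The default smoothing is W = 4 Hz (a ±4 Hz, flat-topped spectral window).
This is the appropriate setting for long, rich recordings, but it makes the
2–7 Hz band essentially a single resolution cell: a narrowband coupling at
4–5 Hz appears as a plateau whose lower edge lies below the measurable range,
and any estimator of its position is then compressed (slope ≈ 0.5 per Hz of
true shift) and biased upward by 1–2 Hz. This is a property of the window,
not of the peak fitter — an oracle least-squares fit shows the same behavior.
The bundled scaled study therefore analyzes with W = 2 Hz (±2 Hz, K = 15),
which matches the spectral resolution to the sub-Hz condition spacing of the
synthetic cohorts; with that setting injected CFs of 4.2/4.8/5.3 Hz are
recovered to within ≈0.3 Hz and in the right order. The W value is a config
entry (`smoothing`) recorded in every output sidecar.

## Spectral parametrization

A coherence spectrum is fit in log₁₀ units over 1–20 Hz (values floored at
1e-6) as an aperiodic line `b − χ·log10 f` ("fixed" mode, no knee) plus
Gaussian peaks `a·exp(−(f−c)²/2w²)`:

1. **Robust aperiodic fit** — OLS line, flatten, clip negative residuals at
   zero, refit on the points at or below the 2.5th-percentile residual
   envelope (discounting the peak region).
2. **Iterative peak search** on the flattened spectrum, accepting maxima
   above max(absolute floor = 0, 1.5 × SD of the flattened spectrum), up to
   6 peaks. Peak *locations and extents* are detected on a lightly smoothed
   copy (3-point binomial kernel) so single noise samples riding a broad dome
   do not seed narrow fragments; thresholds use the raw values. The width
   guess is the mean of the two half-height extents.
3. **Joint refinement** of all Gaussians by bounded least squares
   (centers within ±2 guessed widths, widths within the configured limits).
4. **Aperiodic refit** on the peak-subtracted spectrum, one more Gaussian
   refinement round against the new flattening.
5. **Pruning**: the detection threshold is re-applied against the final fit
   residual (whose SD is no longer inflated by the peaks), and of any two
   Gaussians closer than 0.75 × the sum of their widths the taller is kept.
6. **Full-model polish**: one joint bounded least-squares pass over the
   aperiodic parameters and all surviving Gaussians together.

Width limits (default 0.5–6 Hz) bound the Gaussian SD `w` itself; reported
bandwidth is 2w. Fit quality is the squared correlation between spectrum and
model (R²) plus the mean absolute error; non-convergent fits are flagged,
never silently dropped. On noise-free forward-model spectra all five
parameters are recovered to machine precision; with multiplicative log-noise
of SD 0.05 the median CF error over random spectra (CF 3–6.5 Hz, height
0.05–0.3, width 0.5–2 Hz) is ≈ 0.13 Hz with ≥ 95% detection.

Per channel the most prominent peak with center in 2–7 Hz is selected (ties
to the lower CF; none → the channel is excluded from peak-parameter averages,
not zero-filled). Channels whose R² or MAE deviates from the within-subject
mean by more than 2.5 SD are dropped in one pass with a reasoned log. Peak
parameters are averaged over channels with a selected peak, aperiodic
parameters over all retained channels.

## The synthetic-data generator

The generator's purpose is to produce data with the statistical structure the
analysis assumes, at knowable ground truth. Per subject × condition cell:

- **Envelope** = rectified sum of (i) a power-law floor (β = 1) with a
  second-order low-frequency shoulder at 2.5 Hz — speech modulation spectra
  roll off below a few Hz rather than diverging; (ii) a narrowband
  *modulation peak* (default 5.5 Hz, width 2 Hz, amplitude 0.8) — the
  acoustic modulation rate; (iii) a narrowband *tracking component* at the
  condition's (jittered) tracking CF, amplitude 0.5 — envelope energy the
  channels lock to, analogous to syllable-band energy; (iv) a shared *slow
  drive* (β = 2, amplitude 0.8) — prosodic-scale fluctuations; (v) a weak
  shared broadband comodulation (amplitude 0.4); (vi) a unit baseline.
- **Channels** = sqrt(coupling_snr)·tracking + sqrt(aperiodic_snr)·slow +
  sqrt(broadband_snr)·broadband + power-law noise (β = 1, shoulder 1.5 Hz —
  recorded neural data are high-pass filtered, so the background flattens
  below ~1.5 Hz rather than diverging).

The slow shared drive gives the coherence spectrum its 1/f-like aperiodic
component; the broadband comodulation raises the coherence floor into the
peak-to-floor contrast regime (≈ 0.3–0.7 log units) that real coherence
spectra occupy and the log-domain parametrization is built for. Between
subjects, the tracking CF is jittered by a Gaussian of SD 0.2 Hz and all
three SNRs by a common log-normal factor of log-SD 0.2 (an overall-gain
trait). One integer seed expands into per-subject × condition substreams via
`SeedSequence` spawn keys, so any subset of a cohort is reproducible.

**Across conditions** the bundled study varies the tracking CF
(4.2 → 4.8 → 5.3 Hz) and scales coupling, aperiodic and broadband SNR *down
together* (0.20/0.5/0.06 → 0.14/0.35/0.042 → 0.10/0.25/0.03). A common gain
loss moves band coherence and the aperiodic offset while leaving the
*relative* peak height unchanged — which is exactly the dissociation the
parametrization is meant to expose: band averages track the aperiodic
background, the peak CF tracks the tracking frequency.

What the generator does **not** emulate: sensor physics, source leakage,
correlated channel noise, non-stationarity within a recording, phonetic or
lexical structure in the envelope, or attention-like state changes. Passing
tests therefore show the *analysis chain* is correct and calibrated under
the stated statistical structure, not that real recordings satisfy that
structure.

Other fixtures: syllable-like **burst audio** (Hann-windowed bursts at a
known rate on a −34 dB floor, noise or harmonic carrier, with the ground-
truth gate returned), **multiband audio** with an independent slow envelope
in each of 7 cochlear bands (the fixture under which vocoder channel count
matters), and binomial **behavior tables**.

## Vocoder

Greenwood-mapped band edges (A = 165.4, α = 2.1, k = 0.88 over normalized
position) give equal cochlear spacing between 200 and 7000 Hz. Per band:
zero-phase 4th-order Butterworth band-pass, half-wave rectification, 250 Hz
low-pass, normalization by the envelope maximum, multiplication with a seeded
white-noise carrier, re-filtering into the band, and RMS matching to the
band-filtered original (exact to machine precision by construction); bands
are summed. Silent input maps to silent output without division by zero.

Envelope preservation is quantified per band: the mean ≤10 Hz envelope
correlation across a fixed 7-band analysis filterbank
(`band_envelope_correlation`). Under this measure fidelity degrades
monotonically with channel count (≈ 0.98 / 0.63 / 0.40 for 7/3/1 channels on
the multiband fixture). The *broadband* envelope is not a useful fidelity
measure here: a single-channel vocoder multiplies its carrier by precisely
that envelope and so preserves it almost perfectly.

## Stimulus rates

- **Modulation spectrum**: 32 Greenwood-spaced bands (200–7000 Hz), band
  envelopes as magnitude of the analytic signal, low-passed at 25 Hz and
  resampled to 100 Hz; per 6-s segment the DC-removed FFT magnitudes are
  RMS-combined across bands, averaged over segments, and normalized to unit
  maximum (resolution 1/6 Hz). Low-rate inputs (already-extracted envelopes)
  skip the filterbank. The **modulation rate** is the global maximum within
  a band, ties to the lower frequency, band-edge maxima flagged with a
  warning.
- **Syllable rate**: frame-RMS intensity contour in dB relative to the
  loudest frame (32 ms frames, 10 ms hop); local maxima above −25 dB count
  as nuclei if the contour dips ≥ 2 dB between them; an optional voicing
  gate (autocorrelation periodicity in the 75–500 Hz lag range ≥ 0.3) is off
  by default because synthetic carriers need not be voiced. All thresholds
  are relative, so the estimate is gain-invariant.

## Inference battery

All tests are written from their sums-of-squares / ranking definitions and
cross-checked against brute-force oracles (nested-OLS ANOVA decompositions,
exhaustive sign/rank enumerations, all-orderings dominance) and against an
independent implementation in the test suite.

- RM-ANOVAs report the within-subject F, Greenhouse–Geisser ε (from the
  double-centered condition covariance; for the two-way interaction from the
  Helmert-contrast Kronecker subspace), the GG-corrected p and partial η².
  Degenerate tables return F = 0, p = 1 (no effect variance) or F = ∞,
  p = 0 (no error variance) rather than NaN.
- Post-hocs: paired t with Cohen's d on the paired differences, or Wilcoxon
  with rank-biserial effect size; Benjamini–Hochberg step-up adjustment with
  enforced monotonicity. Zero-variance nonzero differences under t raise an
  error directing to the Wilcoxon path.
- The cluster-based permutation test thresholds per-unit RM-ANOVA F values at
  the parametric critical value (one-sided, cluster α = 0.05), forms
  connected components under a caller-supplied adjacency (None = 1-D chain),
  and compares observed cluster masses (ΣF) to the maximum-mass null from
  within-subject label shuffles; p = (1 + #{null ≥ obs})/(n_perm + 1), never
  zero. Family-wise error on null data (12 subjects × 3 conditions × 100-bin
  chain, 500 permutations × 200 simulations) measures ≈ 0.05.
- Repeated-measures correlation: within-subject centering (the ANCOVA
  formulation with subject as blocking factor), df = N − k − 1; subjects
  with one observation are dropped with a warning.
- Dominance analysis computes subset R² directly from the correlation matrix
  (`r_yS' R_SS⁻¹ r_yS` over all subsets) and averages incremental R² over
  subset sizes; the weights sum to the full-model R² to 1e-10, and singular
  subsets raise an error naming the offending predictors.

## Rate decoder

An ensemble of 50 k-nearest-neighbor classifiers over the single feature
(frequency, Hz). Each member holds out a stratified 10% test split, selects
its neighbor count (odd k from 1 to min(31, n/2) — a grid the data cannot
pin down more precisely) by mean ROC-AUC over a 5-fold stratified CV
repeated 25 times, refits, and is scored on its held-out split; confusion
matrices and AUCs are averaged across members. The inner search scores every
k from a single neighbor ranking per fold (cumulative-vote identity), which
is why the nested procedure runs in seconds. Applied to neural CFs the
ensemble returns averaged class probabilities (rows sum to 1) with values
outside the training support flagged as extrapolation.

## Aperiodic simulations

`simulate_pair` builds x = √snr·s + nₓ, y = √snr·s + n_y from independent
power-law noises, optionally plus a shared narrowband component. Power-law
noise is synthesized by spectral shaping of white noise (amplitude ∝
f^(−β/2), DC zeroed), with an optional second-order low-frequency shoulder.
Across a 5-point SNR grid (50 reps/point, 480-s signals, ±2 Hz smoothing),
with the coupling amplitude scaling as √snr (the same overall-gain model as
the cohort), the fitted aperiodic offset increases strictly monotonically
while the injected 4.5 Hz peak's mean CF moves < 0.25 Hz. With a constant
coupling amplitude the peak-to-background contrast varies along the grid and
the apparent CF drifts by up to ~0.5 Hz — a deliberate illustration that
log-domain peak location is only stable at comparable contrast.
`highpass_sensitivity` shows that moving the high-pass cutoff from 0.1 to
1 Hz shifts offset and exponent while leaving the selected peak's CF in
place.

## Problem sizes and defaults

The bundled study uses 12 subjects × 3 conditions × 60 epochs of 4 s × 4
channels at 100 Hz — sizes chosen so a full cohort analyzes in a few seconds
and 50-cohort power checks in a few minutes while keeping every inferential
step non-trivial (GG correction, FDR, equalization all engage). Jitter
magnitudes (0.2 Hz CF, 0.2 log-SNR) are generator choices exposed in
`CohortSpec`; no per-subject variance estimates exist to calibrate them
against, so they were set once to give realistic within/between variance
ratios for repeated-measures statistics and not revisited.

## Known limitations

- CF recovery through the ±4 Hz default smoothing is compressed and biased
  for narrowband couplings (see above); within-study *contrasts* survive,
  absolute CFs do not.
- The aperiodic model is a straight line in log–log space; knee-shaped
  backgrounds are out of scope and will bias χ.
- The decoder is single-feature by design; it cannot exceed the overlap
  limit of the two rate distributions.
- Magnitude coherence is bias-positive at small epoch counts; comparisons
  across different epoch counts require the equalization step.
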