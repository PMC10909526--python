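"""Periodic/aperiodic decomposition of coherence spectra.

A coherence spectrum is modeled, in log10 units, as an aperiodic component
``b - chi * log10(f)`` (offset ``b``, exponent ``chi``; "fixed" mode, no knee)
plus a sum of Gaussian peaks ``a * exp(-(f - c)^2 / (2 w^2))`` parameterized
by center frequency ``c`` (Hz), height ``a`` (log10 units above the aperiodic
component) and width ``w`` (Gaussian SD, Hz; reported bandwidth is ``2 w``).

The fitting procedure:

1. log10-transform the spectrum (floored at a small epsilon);
2. robust aperiodic fit — an ordinary least-squares line is fit, the spectrum
   is flattened, negative residuals are clipped at zero, and the line is
   refit using only the points at or below the 2.5th-percentile residual
   envelope, which discounts the peak region;
3. iterative peak search on the flattened spectrum — the maximum is accepted
   while it exceeds max(absolute floor, peak_threshold * SD of the flattened
   spectrum); a Gaussian guess (height at the maximum, width from the
   half-height extent) is subtracted and the search repeats up to
   ``max_n_peaks``;
4. all Gaussian guesses are refined jointly by bounded least squares on the
   flattened spectrum;
5. the aperiodic component is refit on the peak-subtracted spectrum, the
   Gaussians are refined once more against the new flattening, and the
   aperiodic fit is repeated (one fixed-point round improves noise-free
   recovery);
6. the full model is aperiodic + Gaussians; fit quality is reported as R^2
   (squared correlation between spectrum and model) and mean absolute error.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .cohspec import CoherenceSpectrum

__all__ = [
    "Peak",
    "ParamFit",
    "fit_spectrum",
    "parametrize_spectrum",
    "select_band_peak",
    "qc_drop",
    "channel_average",
]


@dataclass
class Peak:
    cf: float  # center frequency, Hz
    height: float  # log10 units above the aperiodic component
    width: float  # Gaussian SD, Hz

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.width


@dataclass
class ParamFit:
    """Aperiodic + periodic decomposition of one coherence spectrum."""

    offset: float
    exponent: float
    peaks: list[Peak]
    r2: float
    mae: float
    flagged: bool = False
    selected: "int | None" = None
    fit_range: tuple[float, float] = (1.0, 20.0)
    channel: int = 0
    condition: str = ""
    subject_id: str = ""

    @property
    def selected_peak(self) -> "Peak | None":
        return None if self.selected is None else self.peaks[self.selected]


def _aperiodic(logf: np.ndarray, b: float, chi: float) -> np.ndarray:
    return b - chi * logf


def _gauss_sum(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for c, a, w in params.reshape(-1, 3):
        out += a * np.exp(-((f - c) ** 2) / (2.0 * w**2))
    return out


def _simple_ap_fit(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # least-squares line y = b - chi * logf
    A = np.column_stack([np.ones_like(logf), -logf])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_ap_fit(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    b0, chi0 = _simple_ap_fit(logf, y)
    flat = y - _aperiodic(logf, b0, chi0)
    flat = np.where(flat < 0, 0.0, flat)
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() < 2:
        return b0, chi0
    return _simple_ap_fit(logf[mask], y[mask])


def _guess_peaks(
    f: np.ndarray,
    flat: np.ndarray,
    peak_threshold: float,
    min_peak_height: float,
    width_limits: tuple[float, float],
    max_n_peaks: int,
) -> list[tuple[float, float, float]]:
    # peak locations and extents are detected on a lightly smoothed copy
    # (3-point binomial kernel) so single noise samples riding a broad dome
    # do not seed narrow fragments; heights/thresholds use the raw values
    flat = flat.copy()
    flat_s = np.convolve(flat, [0.25, 0.5, 0.25], mode="same")
    w_lo, w_hi = width_limits  # limits on the Gaussian SD
    guesses: list[tuple[float, float, float]] = []
    for _ in range(max_n_peaks):
        i = int(np.argmax(flat_s))
        h = flat[i]
        if h <= max(min_peak_height, peak_threshold * np.std(flat)):
            break
        c = f[i]
        # half-height extent on each side
        half = flat_s[i] / 2.0
        li = i
        while li > 0 and flat_s[li] > half:
            li -= 1
        ri = i
        while ri < f.size - 1 and flat_s[ri] > half:
            ri += 1
        # average the two half-height extents (falling back to one side at a
        # spectrum edge) so broad smooth peaks get one wide Gaussian instead
        # of a stack of narrow fragments; the joint refinement sharpens any
        # genuinely overlapping peaks afterwards
        sides = []
        if li != i:
            sides.append(c - f[li])
        if ri != i:
            sides.append(f[ri] - c)
        hwhm = float(np.mean(sides)) if sides else (f[1] - f[0])
        w = float(np.clip(hwhm / np.sqrt(2 * np.log(2)), w_lo, w_hi))
        guesses.append((float(c), float(h), w))
        gauss = h * np.exp(-((f - c) ** 2) / (2.0 * w**2))
        flat = flat - gauss
        flat_s = flat_s - gauss
    return guesses


def _drop_overlap(
    peaks: list[tuple[float, float, float]], thresh: float = 0.75
) -> list[tuple[float, float, float]]:
    """Drop the smaller of any two Gaussians whose centers overlap.

    Two peaks overlap when their center distance is below ``thresh`` times
    the sum of their widths; the taller one is kept. Prevents one broad peak
    from being represented as a stack of shoulder-riding fragments.
    """
    kept = sorted(peaks, key=lambda p: p[0])
    changed = True
    while changed and len(kept) > 1:
        changed = False
        for i in range(len(kept) - 1):
            (c1, a1, w1), (c2, a2, w2) = kept[i], kept[i + 1]
            if c2 - c1 < thresh * (w1 + w2):
                kept.pop(i if a1 < a2 else i + 1)
                changed = True
                break
    return kept


def _refine_peaks(
    f: np.ndarray,
    flat: np.ndarray,
    guesses: list[tuple[float, float, float]],
    width_limits: tuple[float, float],
) -> tuple[list[tuple[float, float, float]], bool]:
    """Jointly refine Gaussian guesses by bounded least squares on ``flat``."""
    if not guesses:
        return [], False
    w_lo, w_hi = width_limits
    p0, lo, hi = [], [], []
    for c, a, w in guesses:
        p0 += [c, a, w]
        lo += [max(c - 2 * w, f[0]), 0.0, w_lo]
        hi += [min(c + 2 * w, f[-1]), max(2.5 * a, 1e-6), w_hi]
    p0 = np.clip(p0, lo, hi)

    def model(x, *params):
        return _gauss_sum(x, np.asarray(params))

    try:
        popt, _ = curve_fit(model, f, flat, p0=p0, bounds=(lo, hi), maxfev=5000)
    except RuntimeError:
        return guesses, True
    refined = [tuple(popt[i : i + 3]) for i in range(0, popt.size, 3)]
    return refined, False


def fit_spectrum(
    freqs: np.ndarray,
    values: np.ndarray,
    fit_range: tuple[float, float] = (1.0, 20.0),
    peak_threshold: float = 1.5,
    width_limits: tuple[float, float] = (0.5, 6.0),
    max_n_peaks: int = 6,
    min_peak_height: float = 0.0,
    floor: float = 1e-6,
    log_input: bool = False,
) -> ParamFit:
    """Fit the aperiodic + Gaussian-peaks model to one spectrum.

    ``values`` are coherence (or power) values on the ``freqs`` grid; they are
    floored at ``floor`` and log10-transformed unless ``log_input`` is True.
    ``width_limits`` bound the reported bandwidth 2*w. See the module
    docstring for the algorithm.
    """
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = fit_range
    mask = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if mask.sum() < 5:
        raise ValueError(f"fit range {fit_range} covers fewer than 5 grid points")
    f = freqs[mask]
    y = values[mask] if log_input else np.log10(np.maximum(values[mask], floor))
    logf = np.log10(f)

    b, chi = _robust_ap_fit(logf, y)
    flat = y - _aperiodic(logf, b, chi)
    guesses = _guess_peaks(f, flat, peak_threshold, min_peak_height, width_limits, max_n_peaks)
    peaks_p, flagged = _refine_peaks(f, flat, guesses, width_limits)

    # one fixed-point round: refit aperiodic on the peak-removed spectrum,
    # then refine the peaks against the new flattening
    for _ in range(2):
        gauss = _gauss_sum(f, np.asarray(peaks_p).ravel()) if peaks_p else 0.0
        b, chi = _simple_ap_fit(logf, y - gauss)
        if not peaks_p:
            break
        flat = y - _aperiodic(logf, b, chi)
        peaks_p, flag2 = _refine_peaks(f, flat, peaks_p, width_limits)
        flagged = flagged or flag2

    # final pruning: re-apply the detection threshold against the fit
    # residual, whose SD is no longer inflated by the peaks themselves —
    # this removes noise bumps the iterative search accepted early on
    if peaks_p:
        model_full = _aperiodic(logf, b, chi) + _gauss_sum(f, np.asarray(peaks_p).ravel())
        resid_sd = float(np.std(y - model_full))
        floor_h = max(min_peak_height, peak_threshold * resid_sd)
        kept = _drop_overlap([p for p in peaks_p if p[1] > floor_h])
        if len(kept) != len(peaks_p):
            peaks_p = kept
            flat = y - _aperiodic(logf, b, chi)
            peaks_p, flag3 = _refine_peaks(f, flat, peaks_p, width_limits)
            flagged = flagged or flag3
            gauss = _gauss_sum(f, np.asarray(peaks_p).ravel()) if peaks_p else 0.0
            b, chi = _simple_ap_fit(logf, y - gauss)

    # full-model polish: one joint bounded least-squares pass over the
    # aperiodic parameters and all retained Gaussians together, initialized
    # at the staged estimates — removes the residual bias the alternating
    # scheme leaves on broad peaks
    if peaks_p:
        w_lo, w_hi = width_limits
        p0 = [b, chi]
        lo_b = [-np.inf, -np.inf]
        hi_b = [np.inf, np.inf]
        for c, a, w in peaks_p:
            p0 += [c, a, w]
            lo_b += [lo, 0.0, w_lo]
            hi_b += [hi, np.inf, w_hi]

        def full_model(x, *params):
            return _aperiodic(np.log10(x), params[0], params[1]) + _gauss_sum(
                x, np.asarray(params[2:])
            )

        try:
            popt, _ = curve_fit(
                full_model, f, y, p0=np.clip(p0, lo_b, hi_b),
                bounds=(lo_b, hi_b), maxfev=5000,
            )
            b, chi = float(popt[0]), float(popt[1])
            peaks_p = [tuple(popt[i : i + 3]) for i in range(2, popt.size, 3)]
        except RuntimeError:
            flagged = True

    peaks = [
        Peak(cf=float(c), height=float(a), width=float(w))
        for c, a, w in peaks_p
        if a > 0 and lo <= c <= hi
    ]
    peaks.sort(key=lambda p: p.cf)
    peak_arr = np.asarray([[p.cf, p.height, p.width] for p in peaks]).ravel()
    model = _aperiodic(logf, b, chi) + (_gauss_sum(f, peak_arr) if peaks else 0.0)
    resid = y - model
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(np.corrcoef(y, model)[0, 1] ** 2) if ss_tot > 0 and np.std(model) > 0 else 1.0
    mae = float(np.mean(np.abs(resid)))
    return ParamFit(
        offset=float(b),
        exponent=float(chi),
        peaks=peaks,
        r2=r2,
        mae=mae,
        flagged=flagged,
        fit_range=(float(lo), float(hi)),
    )


def parametrize_spectrum(
    cs: CoherenceSpectrum,
    fit_range: tuple[float, float] = (1.0, 20.0),
    peak_threshold: float = 1.5,
    width_limits: tuple[float, float] = (0.5, 6.0),
    max_n_peaks: int = 6,
    min_peak_height: float = 0.0,
    floor: float = 1e-6,
) -> list[ParamFit]:
    """Fit every channel of a :class:`CoherenceSpectrum`; returns one ParamFit per channel."""
    fits = []
    for ch in range(cs.coh.shape[0]):
        fit = fit_spectrum(
            cs.freqs,
            cs.coh[ch],
            fit_range=fit_range,
            peak_threshold=peak_threshold,
            width_limits=width_limits,
            max_n_peaks=max_n_peaks,
            min_peak_height=min_peak_height,
            floor=floor,
        )
        fit.channel = ch
        fit.condition = cs.condition
        fit.subject_id = cs.subject_id
        fits.append(fit)
    return fits


def select_band_peak(fit: ParamFit, band: tuple[float, float] = (2.0, 7.0)) -> "Peak | None":
    """Select the most prominent (highest) peak with cf inside ``band``.

    Ties resolve to the lower center frequency. Returns None (and leaves
    ``fit.selected`` as None) when no peak falls in the band; such channels
    are excluded from peak-parameter averages rather than zero-filled.
    """
    lo, hi = band
    best: "int | None" = None
    for i, p in enumerate(fit.peaks):
        if not (lo <= p.cf <= hi):
            continue
        if best is None or p.height > fit.peaks[best].height or (
            p.height == fit.peaks[best].height and p.cf < fit.peaks[best].cf
        ):
            best = i
    fit.selected = best
    return None if best is None else fit.peaks[best]


def qc_drop(fits: list[ParamFit], n_sd: float = 2.5) -> tuple[list[ParamFit], list[dict]]:
    """Drop fits whose R^2 or MAE deviates from the group mean by > ``n_sd`` SDs.

    A single pass over the collection; returns (retained fits, drop log).
    Requires at least 3 fits (the SD-based rule is undefined below that).
    """
    if len(fits) < 3:
        raise ValueError("qc_drop needs at least 3 fits")
    r2 = np.array([f.r2 for f in fits])
    mae = np.array([f.mae for f in fits])
    r2_m, r2_sd = r2.mean(), r2.std(ddof=1)
    mae_m, mae_sd = mae.mean(), mae.std(ddof=1)
    retained: list[ParamFit] = []
    log: list[dict] = []
    for f, r, m in zip(fits, r2, mae):
        reasons = []
        if r2_sd > 0 and abs(r - r2_m) > n_sd * r2_sd:
            reasons.append(f"r2 {r:.4f} deviates > {n_sd} SD from mean {r2_m:.4f}")
        if mae_sd > 0 and abs(m - mae_m) > n_sd * mae_sd:
            reasons.append(f"mae {m:.4g} deviates > {n_sd} SD from mean {mae_m:.4g}")
        if f.flagged:
            reasons.append("non-convergent joint fit")
        if reasons:
            log.append(
                {"subject_id": f.subject_id, "condition": f.condition,
                 "channel": f.channel, "reasons": reasons}
            )
        else:
            retained.append(f)
    if not retained:
        raise ValueError("qc_drop removed every fit")
    return retained, log


def channel_average(fits: list[ParamFit], band: tuple[float, float] = (2.0, 7.0)) -> dict:
    """Average peak and aperiodic parameters across channels for one subject.

    Peaks are selected per channel with :func:`select_band_peak`; CF, height
    and bandwidth are averaged over channels with a selected peak, while
    offset and exponent are averaged over all retained channels. Peak fields
    are NaN when no channel has a band peak.
    """
    if not fits:
        raise ValueError("no fits to average")
    sel = []
    for f in fits:
        p = select_band_peak(f, band)
        if p is not None:
            sel.append(p)
    out = {
        "offset": float(np.mean([f.offset for f in fits])),
        "exponent": float(np.mean([f.exponent for f in fits])),
        "r2_mean": float(np.mean([f.r2 for f in fits])),
        "mae_mean": float(np.mean([f.mae for f in fits])),
        "n_channels": len(fits),
        "n_channels_valid": len(sel),
    }
    if sel:
        out["cf"] = float(np.mean([p.cf for p in sel]))
        out["height"] = float(np.mean([p.height for p in sel]))
        out["bandwidth"] = float(np.mean([p.bandwidth for p in sel]))
    else:
        out["cf"] = out["height"] = out["bandwidth"] = float("nan")
    return out
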