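"""Periodic/aperiodic decomposition: recovery, selection, QC, averaging."""

import numpy as np
import pytest

import trackshift as ts
from trackshift.paramfit import Peak, ParamFit


def forward_spectrum(freqs, b, chi, peaks, log_noise=0.0, rng=None):
    """Exact forward model: aperiodic line plus Gaussian peaks, in log10 units."""
    logv = b - chi * np.log10(np.maximum(freqs, 1e-9))
    for c, a, w in peaks:
        logv = logv + a * np.exp(-((freqs - c) ** 2) / (2 * w**2))
    if log_noise:
        logv = logv + log_noise * rng.standard_normal(freqs.size)
    return 10.0**logv


class TestNoiseFreeRecovery:
    @pytest.mark.parametrize(
        "b,chi,c,a,w",
        [
            (-1.2, 0.8, 4.2, 0.15, 0.8),
            (-1.5, 1.5, 3.2, 0.30, 1.5),
            (-1.0, 0.5, 6.0, 0.08, 0.6),
            (-2.0, 2.0, 5.0, 0.20, 2.0),
        ],
    )
    def test_single_peak_parameters_recovered(self, freqs25, b, chi, c, a, w):
        vals = forward_spectrum(freqs25, b, chi, [(c, a, w)])
        fit = ts.fit_spectrum(freqs25, vals)
        assert len(fit.peaks) == 1
        p = fit.peaks[0]
        assert abs(p.cf - c) <= 0.05
        assert abs(p.height - a) <= 0.05 * a
        assert abs(p.width - w) <= 0.10 * w
        assert abs(fit.offset - b) <= 0.02
        assert abs(fit.exponent - chi) <= 0.05 * chi
        assert fit.r2 > 0.999

    def test_two_peaks_separated(self, freqs25):
        vals = forward_spectrum(freqs25, -1.2, 0.8, [(4.2, 0.15, 0.8), (9.0, 0.2, 1.2)])
        fit = ts.fit_spectrum(freqs25, vals)
        cfs = sorted(p.cf for p in fit.peaks)
        assert len(cfs) == 2
        assert abs(cfs[0] - 4.2) <= 0.1 and abs(cfs[1] - 9.0) <= 0.1

    def test_pure_aperiodic_yields_no_peaks(self, freqs25):
        vals = forward_spectrum(freqs25, -1.2, 0.8, [])
        fit = ts.fit_spectrum(freqs25, vals)
        assert fit.peaks == []
        assert abs(fit.offset + 1.2) <= 1e-6
        assert abs(fit.exponent - 0.8) <= 1e-6


def test_noisy_recovery_median_within_grid_step(freqs25):
    rng = np.random.default_rng(9)
    errs = []
    for _ in range(60):
        vals = forward_spectrum(freqs25, -1.2, 0.8, [(4.2, 0.15, 0.8)],
                                log_noise=0.05, rng=rng)
        fit = ts.fit_spectrum(freqs25, vals)
        p = ts.select_band_peak(fit)
        errs.append(abs(p.cf - 4.2) if p is not None else np.nan)
    assert np.sum(np.isnan(errs)) <= 6
    assert np.nanmedian(errs) <= 0.25


def test_height_invariant_to_global_rescaling(freqs25):
    vals = forward_spectrum(freqs25, -1.2, 0.8, [(4.2, 0.15, 0.8)])
    f1 = ts.fit_spectrum(freqs25, vals)
    f2 = ts.fit_spectrum(freqs25, 0.3 * vals)
    # a constant factor is absorbed by the offset, not the peak height
    assert abs(f2.offset - (f1.offset + np.log10(0.3))) <= 0.02
    assert abs(f2.peaks[0].height - f1.peaks[0].height) <= 0.01


class TestSelectBandPeak:
    def _fit(self, peaks):
        return ParamFit(offset=-1.0, exponent=1.0, peaks=peaks, r2=0.99, mae=0.01)

    def test_most_prominent_in_band(self):
        fit = self._fit([Peak(3.0, 0.1, 0.5), Peak(5.0, 0.2, 0.5)])
        assert ts.select_band_peak(fit).cf == 5.0

    def test_out_of_band_peak_not_selected(self):
        fit = self._fit([Peak(8.0, 0.3, 0.5)])
        assert ts.select_band_peak(fit) is None
        assert fit.selected is None

    def test_tie_resolves_to_lower_cf(self):
        fit = self._fit([Peak(3.0, 0.2, 0.5), Peak(5.0, 0.2, 0.5)])
        assert ts.select_band_peak(fit).cf == 3.0

    def test_bandwidth_is_twice_width(self):
        assert Peak(4.0, 0.1, 0.8).bandwidth == 1.6


class TestQcDrop:
    def _fits(self, r2s, maes=None):
        maes = maes or [0.01] * len(r2s)
        return [ParamFit(offset=-1, exponent=1, peaks=[], r2=r, mae=m)
                for r, m in zip(r2s, maes)]

    def test_identical_fits_all_retained(self):
        kept, log = ts.qc_drop(self._fits([0.95] * 10))
        assert len(kept) == 10 and log == []

    def test_low_r2_outlier_dropped(self):
        rng = np.random.default_rng(0)
        r2s = list(0.95 + 0.001 * rng.standard_normal(9)) + [0.5]
        kept, log = ts.qc_drop(self._fits(r2s))
        assert len(kept) == 9
        assert len(log) == 1 and "r2" in log[0]["reasons"][0]

    def test_two_fits_raise(self):
        with pytest.raises(ValueError):
            ts.qc_drop(self._fits([0.9, 0.8]))


class TestChannelAverage:
    def _fit(self, cf, height=0.2, width=0.5, offset=-1.0, exponent=1.0):
        return ParamFit(offset=offset, exponent=exponent,
                        peaks=[Peak(cf, height, width)], r2=0.99, mae=0.01)

    def test_single_channel_identity(self):
        avg = ts.channel_average([self._fit(4.0)])
        assert avg["cf"] == 4.0 and avg["n_channels_valid"] == 1

    def test_mean_over_channels(self):
        avg = ts.channel_average([self._fit(4.0), self._fit(5.0)])
        assert avg["cf"] == 4.5

    def test_order_invariance(self):
        fits = [self._fit(4.0, offset=-1.0), self._fit(5.0, offset=-2.0)]
        a = ts.channel_average(fits)
        b = ts.channel_average(fits[::-1])
        assert a == b

    def test_no_band_peak_yields_missing_values(self):
        fit = ParamFit(offset=-1, exponent=1, peaks=[Peak(9.0, 0.2, 0.5)],
                       r2=0.99, mae=0.01)
        avg = ts.channel_average([fit])
        assert np.isnan(avg["cf"]) and avg["n_channels_valid"] == 0
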