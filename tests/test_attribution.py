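"""Rate attribution: absolute differences, variance explained, the kNN decoder."""

import numpy as np
import pandas as pd
import pytest

import trackshift as ts


def _cf_table(cfs, conds=("a", "b", "c"), n_subj=None):
    rows = []
    n_subj = n_subj or len(cfs) // len(conds)
    i = 0
    for s in range(n_subj):
        for c in conds:
            rows.append({"subject": f"s{s}", "condition": c, "cf": cfs[i]})
            i += 1
    return pd.DataFrame(rows)


class TestAbsDiffTable:
    RATES = {"a": (5.5, 4.0), "b": (5.5, 4.0), "c": (5.5, 4.0)}

    def test_arithmetic(self):
        tab = ts.abs_diff_table(_cf_table([4.5, 5.5, 4.0]), self.RATES)
        assert tab.loc[0, "abs_diff_mod"] == 1.0
        assert tab.loc[0, "abs_diff_syll"] == 0.5
        assert tab.loc[1, "abs_diff_mod"] == 0.0

    def test_missing_cf_retained_as_nan(self):
        tab = ts.abs_diff_table(_cf_table([4.5, np.nan, 4.0]), self.RATES)
        assert len(tab) == 3
        assert np.isnan(tab.loc[1, "abs_diff_mod"])

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError, match="missing"):
            ts.abs_diff_table(_cf_table([4.5, 5.5, 4.0]), {"a": (5.5, 4.0)})


class TestVocodingSlope:
    def test_constant_coherence_zero_slope(self):
        tab = _cf_table([1, 1, 1, 1, 1, 1]).rename(columns={"cf": "band_coh"})
        slopes = ts.vocoding_slope(tab, ["a", "b", "c"])
        assert np.allclose(slopes, 0.0)

    def test_linear_decline(self):
        tab = _cf_table([0.3, 0.2, 0.1]).rename(columns={"cf": "band_coh"})
        slopes = ts.vocoding_slope(tab, ["a", "b", "c"])
        assert abs(slopes.iloc[0] + 0.1) <= 1e-12

    def test_missing_condition_gives_nan(self):
        tab = _cf_table([0.3, 0.2, 0.1]).rename(columns={"cf": "band_coh"})
        slopes = ts.vocoding_slope(tab[tab.condition != "b"], ["a", "b", "c"])
        assert np.isnan(slopes.iloc[0])


class TestVarianceExplained:
    def test_exact_dependence_gives_unit_r2(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(6):
            for c in range(3):
                off = rng.standard_normal()
                rows.append({"subject": f"s{s}", "condition": c,
                             "offset": off, "band_coh": 2.0 * off + s})
        out = ts.aperiodic_variance_explained(pd.DataFrame(rows), params=("offset",))
        assert out.loc[0, "r2"] > 1 - 1e-9

    def test_independent_parameter_near_zero(self):
        rng = np.random.default_rng(1)
        r2s = []
        for rep in range(30):
            rows = [{"subject": f"s{s}", "condition": c,
                     "height": rng.standard_normal(),
                     "band_coh": rng.standard_normal()}
                    for s in range(8) for c in range(3)]
            out = ts.aperiodic_variance_explained(pd.DataFrame(rows), params=("height",))
            r2s.append(out.loc[0, "r2"])
        assert np.median(r2s) <= 0.05


class TestDecoder:
    SETTINGS = ts.DecoderSettings(n_members=10, repetitions=5)

    def test_separable_classes_high_auc(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(5.5, 0.3, 100), rng.normal(4.0, 0.2, 100)])
        labels = np.array(["modulation"] * 100 + ["syllable"] * 100)
        dec = ts.train_rate_decoder(vals, labels, self.SETTINGS, seed=3)
        assert dec.test_auc >= 0.9
        probs = ts.apply_decoder(dec, [4.0, 5.5])
        assert probs.loc[0, "p_syllable"] > 0.5
        assert probs.loc[1, "p_modulation"] > 0.5

    def test_same_seed_reproduces_ensemble(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(5.5, 0.3, 60), rng.normal(4.0, 0.2, 60)])
        labels = np.array(["modulation"] * 60 + ["syllable"] * 60)
        d1 = ts.train_rate_decoder(vals, labels, self.SETTINGS, seed=9)
        d2 = ts.train_rate_decoder(vals, labels, self.SETTINGS, seed=9)
        assert d1.neighbor_counts == d2.neighbor_counts
        np.testing.assert_array_equal(d1.confusion, d2.confusion)

    def test_probabilities_sum_to_one_and_flag_extrapolation(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(5.5, 0.3, 60), rng.normal(4.0, 0.2, 60)])
        labels = np.array(["modulation"] * 60 + ["syllable"] * 60)
        dec = ts.train_rate_decoder(vals, labels, self.SETTINGS, seed=9)
        probs = ts.apply_decoder(dec, [3.0, 4.5, 12.0])
        np.testing.assert_allclose(probs["p_modulation"] + probs["p_syllable"], 1.0)
        assert bool(probs.loc[2, "extrapolated"]) and not bool(probs.loc[1, "extrapolated"])

    def test_midpoint_of_overlapping_classes_near_half(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(5.5, 0.4, 150), rng.normal(4.5, 0.4, 150)])
        labels = np.array(["modulation"] * 150 + ["syllable"] * 150)
        dec = ts.train_rate_decoder(vals, labels, self.SETTINGS, seed=4)
        probs = ts.apply_decoder(dec, [5.0])
        assert 0.35 <= probs.loc[0, "p_modulation"] <= 0.65

    def test_imbalance_and_count_validation(self):
        labels = np.array(["modulation"] * 100 + ["syllable"] * 20)
        with pytest.raises(ValueError, match="imbalance"):
            ts.train_rate_decoder(np.arange(120.0), labels, self.SETTINGS, seed=0)
        labels = np.array(["modulation"] * 10 + ["syllable"] * 10)
        with pytest.raises(ValueError, match="20"):
            ts.train_rate_decoder(np.arange(20.0), labels, self.SETTINGS, seed=0)
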