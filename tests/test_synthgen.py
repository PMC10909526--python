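"""Generator contracts: modulation peaks, coupling, bursts, behavior tables."""

import numpy as np
import pytest

import trackshift as ts


class TestEnvelope:
    def test_modulation_peak_recovered(self):
        env = ts.gen_envelope(100.0, 60.0, mod_rate=4.0, mod_bw=0.5, exponent=1.0, seed=1)
        freqs, spec, n_seg = ts.modulation_spectrum(env.samples, env.rate)
        cf = ts.center_frequency(freqs, spec, (2.0, 7.0))
        assert 3.75 <= cf <= 4.25
        assert n_seg == 10
        assert np.all(env.samples >= 0)

    def test_zero_depth_leaves_no_band_peak(self):
        env = ts.gen_envelope(100.0, 60.0, mod_rate=4.0, seed=2, mod_depth=0.0)
        freqs, spec, _ = ts.modulation_spectrum(env.samples, env.rate)
        band = spec[(freqs >= 2) & (freqs <= 7)]
        surround = np.median(spec[(freqs >= 1) & (freqs <= 12)])
        assert band.max() < 2.0 * surround

    def test_same_seed_is_bit_identical(self):
        a = ts.gen_envelope(100.0, 20.0, 4.0, seed=7)
        b = ts.gen_envelope(100.0, 20.0, 4.0, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rate": 0.0, "duration": 20.0, "mod_rate": 4.0},
            {"rate": 100.0, "duration": 5.0, "mod_rate": 4.0},
            {"rate": 100.0, "duration": 20.0, "mod_rate": 60.0},
            {"rate": 100.0, "duration": 20.0, "mod_rate": 4.0, "mod_depth": -1.0},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            ts.gen_envelope(seed=0, **kwargs)


class TestNeuralEpochs:
    def test_coupling_band_elevated_above_floor(self):
        env = ts.gen_envelope(100.0, 240.0, 5.5, seed=3)
        ep = ts.gen_neural_epochs(env, 1, coupling_cf=5.0, coupling_bw=2.0, snr=1.0, seed=4)
        env_ep = ts.epoch_signal(env.samples, 100.0, 4.0)[: ep.n_epochs]
        cs = ts.mtm_coherence(ep, env_ep)
        at_cf = cs.coh[0, np.argmin(np.abs(cs.freqs - 5.0))]
        floor = cs.coh[0, cs.freqs >= 15].mean()
        assert at_cf > 3.0 * floor

    def test_snr_zero_sits_at_bias_level(self):
        env = ts.gen_envelope(100.0, 240.0, 5.5, seed=3)
        ep = ts.gen_neural_epochs(env, 1, coupling_cf=5.0, snr=0.0, seed=4)
        env_ep = ts.epoch_signal(env.samples, 100.0, 4.0)[: ep.n_epochs]
        cs = ts.mtm_coherence(ep, env_ep)
        band = float(ts.band_average(cs)[0])
        # independent-segments bias: E|coh| ~ sqrt(pi / (4 n)) for n segments
        bias = np.sqrt(np.pi / (4 * ep.n_epochs * cs.n_tapers))
        assert band < 3.0 * bias

    def test_band_coherence_increases_with_snr(self):
        env = ts.gen_envelope(100.0, 240.0, 5.5, seed=3)
        bands = []
        for snr in (0.5, 1.0):
            ep = ts.gen_neural_epochs(env, 1, coupling_cf=5.0, coupling_bw=2.0,
                                      snr=snr, seed=11)
            env_ep = ts.epoch_signal(env.samples, 100.0, 4.0)[: ep.n_epochs]
            bands.append(float(ts.band_average(ts.mtm_coherence(ep, env_ep))[0]))
        assert bands[1] > bands[0]

    def test_errors(self):
        env = ts.gen_envelope(100.0, 20.0, 4.0, seed=0)
        with pytest.raises(ValueError):
            ts.gen_neural_epochs(env, 1, coupling_cf=5.0, snr=-0.1)
        short = ts.Envelope(samples=np.ones(300), rate=100.0)
        with pytest.raises(ValueError):
            ts.gen_neural_epochs(short, 1, coupling_cf=5.0)


class TestCohort:
    def test_structure_and_determinism(self, small_cohort):
        spec, records = small_cohort
        again = ts.gen_cohort(spec)
        assert len(records) == spec.n_subjects * len(spec.conditions)
        for a, b in zip(records, again):
            np.testing.assert_array_equal(a.epochs.data, b.epochs.data)
            np.testing.assert_array_equal(a.envelope.samples, b.envelope.samples)

    def test_true_cfs_jitter_around_condition_values(self, small_cohort):
        spec, records = small_cohort
        for cond in spec.conditions:
            cfs = [r.true_cf for r in records if r.condition == cond.name]
            assert all(abs(c - cond.tracking_cf) < 1.0 for c in cfs)

    def test_single_subject_blocks_rm_anova(self):
        # one subject cannot support a repeated-measures ANOVA downstream
        with pytest.raises(ValueError, match="[Ii]nsufficient|subjects"):
            ts.rm_anova_1way(np.array([[0.1, 0.2, 0.3]]))

    def test_write_cohort_layout(self, small_cohort, tmp_path):
        spec, records = small_cohort
        out = ts.synthgen.write_cohort(records[:3], spec, tmp_path / "cohort")
        assert (out / "manifest.json").exists()
        assert (out / records[0].subject_id / records[0].condition / "epochs.npy").exists()


class TestBurstAudio:
    def test_rate_recovered_within_5pct(self, burst16k):
        est = ts.syllable_rate(burst16k.samples, burst16k.rate)
        assert abs(est - 4.0) <= 0.2

    def test_rates_differ_between_3_and_5_hz(self):
        est = {}
        for r in (3.0, 5.0):
            b = ts.gen_burst_audio(16000.0, 8.0, r, seed=2)
            est[r] = ts.syllable_rate(b.samples, b.rate)
        assert abs((est[5.0] - est[3.0]) - 2.0) <= 0.2

    def test_envelope_tracks_gate(self, burst16k):
        env = ts.extract_envelope(burst16k.samples, burst16k.rate, 100.0)
        gate = burst16k.gate[:: int(burst16k.rate // 100)][: env.samples.size]
        r = np.corrcoef(env.samples[: gate.size], gate)[0, 1]
        assert r > 0.9

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ts.gen_burst_audio(16000.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            ts.gen_burst_audio(16000.0, 8.0, 0.5)
        with pytest.raises(ValueError):
            ts.gen_burst_audio(500.0, 8.0, 4.0)


class TestBehavior:
    def test_graded_hit_rates_power(self):
        detected = 0
        for run in range(50):
            tab = ts.gen_behavior(12, [0.95, 0.85, 0.70], n_trials=24, seed=100 + run)
            wide = tab.pivot(index="subject", columns="condition", values="hit_rate")
            res = ts.rm_anova_1way(wide.to_numpy())
            detected += res.p_gg < 0.05
        assert detected >= 45

    def test_chance_performance_rarely_rejects(self):
        rejects = 0
        for run in range(40):
            tab = ts.gen_behavior(12, [0.5, 0.5, 0.5], n_trials=24, seed=200 + run)
            res = ts.wilcoxon_vs_constant(tab["hit_rate"].to_numpy(), 0.5)
            rejects += res.p < 0.05
        assert rejects <= 8

    def test_validation(self):
        with pytest.raises(ValueError):
            ts.gen_behavior(5, [0.5], n_trials=0)
        with pytest.raises(ValueError):
            ts.gen_behavior(5, [1.5], n_trials=10)
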