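# Bundled scaled study: three vocoding conditions, tracking CF shifting
# from the syllable rate (4 Hz) toward the modulation rate (5.5 Hz)
# while the overall coupling gain drops.
seed: 1
n_subjects: 12
n_epochs: 60
epoch_len: 4.0
n_channels: 4
rate: 100.0
syllable_rate: 4.0
smoothing: 2.0
conditions:
- name: original
  tracking_cf: 4.2
  coupling_snr: 0.2
  aperiodic_snr: 0.5
  broadband_snr: 0.06
  env_mod_rate: 5.5
- name: vocoded7
  tracking_cf: 4.8
  coupling_snr: 0.14
  aperiodic_snr: 0.35
  broadband_snr: 0.042
  env_mod_rate: 5.5
- name: vocoded3
  tracking_cf: 5.3
  coupling_snr: 0.1
  aperiodic_snr: 0.25
  broadband_snr: 0.03
  env_mod_rate: 5.5
behavior:
  hit_prob:
    original: 0.95
    vocoded7: 0.85
    vocoded3: 0.7
  n_trials: 24
decoder:
  enabled: true
  n_members: 10
  repetitions: 5
aperiodic_sim:
  enabled: true
  snr_grid:
  - 0.05
  - 0.1
  - 0.2
  - 0.4
  - 0.8
  n_reps: 10
  duration: 120.0
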