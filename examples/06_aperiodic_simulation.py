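"""How shared-signal SNR shapes the aperiodic part of a coherence spectrum.

Simulates signal pairs sharing a power-law component across a 5-point SNR
grid, with a narrowband coupling at 4.5 Hz whose amplitude scales with the
overall gain. The fitted aperiodic offset climbs with SNR while the periodic
peak's center frequency stays put — the dissociation that makes band-averaged
coherence a poor index of tracking.
"""

import numpy as np

import trackshift as ts

grid = np.array([0.05, 0.1, 0.2, 0.4, 0.8])
amps = 0.8 * np.sqrt(grid / 0.2)
curve = ts.coherence_slope_curve(grid, n_reps=20, duration=240.0, seed=11,
                                 coupling_cf=4.5, coupling_amp=amps, smoothing=2.0)
print(curve[["snr", "offset", "exponent", "band_coh", "peak_cf"]].round(3)
      .to_string(index=False))
print("\nOffset (and band coherence) rise monotonically with the shared SNR;")
print("peak_cf barely moves: the periodic peak, not the band average, indexes")
print("what the second signal tracks.")
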