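"""Noise-vocode audio and check what it does to the envelope.

Vocodes a multiband fixture (independent slow envelopes per cochlear band)
into 7, 3 and 1 channels, verifies the per-band RMS match against the
original, and shows that per-band envelope fidelity — the quantity tied to
intelligibility — drops with channel count even though the broadband
envelope survives.
"""

import numpy as np

import trackshift as ts

rate = 16000.0
audio = ts.gen_multiband_audio(rate, 8.0, seed=0)

for n_channels in (7, 3, 1):
    out, bands = ts.vocode(audio, rate, ts.VocoderSettings(n_channels=n_channels),
                           seed=2, return_bands=True)
    rms_err = max(
        abs(float(np.sqrt(np.mean(info["processed"] ** 2))) - info["rms_target"])
        / info["rms_target"]
        for info in bands.values()
    )
    corr = ts.band_envelope_correlation(audio, out, rate)
    print(f"{n_channels} channel(s): per-band RMS error {rms_err:.1e}, "
          f"band-envelope correlation {corr:.3f}")
print("RMS errors at machine precision show each band's level is preserved;")
print("the falling correlation shows spectral envelope detail lost with fewer channels.")
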