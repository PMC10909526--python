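import numpy as np
import pytest

import trackshift as ts


@pytest.fixture(scope="session")
def freqs25():
    """The analysis frequency grid: 0-25 Hz in 0.25 Hz steps."""
    return np.arange(0.0, 25.25, 0.25)


@pytest.fixture(scope="session")
def burst16k():
    """8 s of 4 Hz syllable-like burst audio at 16 kHz."""
    return ts.gen_burst_audio(16000.0, 8.0, 4.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-condition cohort used across coherence/paramfit tests."""
    spec = ts.CohortSpec(
        n_subjects=4,
        conditions=[
            ts.ConditionSpec("original", 4.2, coupling_snr=0.20, aperiodic_snr=0.5,
                             broadband_snr=0.06, env_mod_rate=5.5),
            ts.ConditionSpec("vocoded7", 4.8, coupling_snr=0.14, aperiodic_snr=0.35,
                             broadband_snr=0.042, env_mod_rate=5.5),
            ts.ConditionSpec("vocoded3", 5.3, coupling_snr=0.10, aperiodic_snr=0.25,
                             broadband_snr=0.03, env_mod_rate=5.5),
        ],
        n_epochs=30,
        n_channels=2,
        seed=5,
    )
    return spec, ts.gen_cohort(spec)

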