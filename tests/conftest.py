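import numpy as np
import pytest

from nirsrr import SimConfig, synthesize_o2hb
from nirsrr.preprocess import main_bandpass


@pytest.fixture
def clean_trial():
    """Noiseless 50 s trial at 18 BPM, band-passed to the analysis band."""
    cfg = SimConfig(resp_rate=0.3, noise_sd=0.0, seed=11)
    sig, truth = synthesize_o2hb(cfg)
    return main_bandpass(sig, cfg.sampling_rate), truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
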