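import numpy as np
import pytest
from hypothesis import settings

from patchlead import synth

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_paired():
    """10 s noiseless, jitter-free, linear paired recording at 60 bpm."""
    cfg = synth.SynthConfig(noise_white_uv=0.0, wander_uv=0.0, rr_jitter=0.0,
                            nonlinearity=0.0, seed=11)
    return synth.synth_paired_recording(cfg)


@pytest.fixture(scope="session")
def noisy_nonlinear_paired():
    """Paired recording with tanh distortion and 10 μV white noise."""
    cfg = synth.SynthConfig(nonlinearity=0.3, noise_white_uv=10.0,
                            wander_uv=0.0, seed=11)
    return synth.synth_paired_recording(cfg)
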