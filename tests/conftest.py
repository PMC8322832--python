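import numpy as np
import pytest

from qrsnet.synthetic import (
    NoiseConfig,
    default_presets,
    interleaved_sequence,
    synth_record,
)

FS = 360.0


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def clean_record():
    """150-beat record (30 per class), no noise, with ground truth."""
    noise = NoiseConfig(baseline_amp=0.0, white_sd=0.0)
    return synth_record(interleaved_sequence(30), None, FS, noise)


@pytest.fixture(scope="session")
def noisy_record():
    """Same protocol with baseline wander and white noise."""
    noise = NoiseConfig(baseline_amp=0.1, white_sd=0.02, seed=11)
    return synth_record(interleaved_sequence(30), None, FS, noise)
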