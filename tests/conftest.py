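import numpy as np
import pytest

from vmstress import SynthConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2 subjects, 5 channels, short trials — fast enough for unit tests."""
    cfg = SynthConfig(
        n_good=2, n_bad=2, fs=128.0,
        duration_baseline_s=6.0, duration_task_s=2.0,
        channels=("EEG Fp1", "EEG F3", "EEG T3", "EEG O1", "ECG ECG"),
        effect_size=3.0, seed=7,
    )
    return generate(cfg)
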