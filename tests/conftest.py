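import numpy as np
import pytest

from respifuse import PipelineConfig, SyntheticConfig, generate_record


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_record():
    """60 s noise-free record, rr=15, hr=60, all modulations on."""
    scfg = SyntheticConfig(duration=60.0, hr_bpm=60.0, rr_bpm=15.0,
                           noise_snr_db=np.inf, seed=7)
    rec, truth = generate_record(scfg)
    return rec, truth, scfg


@pytest.fixture(scope="session")
def noisy_record():
    """60 s record at 20 dB SNR, rr=15, hr=75."""
    scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=15.0,
                           noise_snr_db=20.0, seed=11)
    rec, truth = generate_record(scfg)
    return rec, truth, scfg
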