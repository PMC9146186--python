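import warnings

import numpy as np
import pytest

from fecgkit import ExtractConfig, SynthConfig, extract_fecg, synth_abdominal
from fecgkit.simulate import synth_ecg

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*FastICA did not converge.*")


@pytest.fixture(scope="session")
def clean_fetal():
    """60 s clean fetal ECG at 130 bpm with analytic fiducial truth."""
    x, r, truths = synth_ecg(duration_s=60.0, hr_bpm=130.0, seed=0)
    return x, r, truths


@pytest.fixture(scope="session")
def abdominal_record():
    """Default 30 s four-channel simulated abdominal recording."""
    return synth_abdominal(SynthConfig(duration_s=30.0, seed=0))


@pytest.fixture(scope="session")
def extraction(abdominal_record):
    """Hybrid extraction on the default simulated record."""
    return extract_fecg(abdominal_record.record, ExtractConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
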