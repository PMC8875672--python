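import numpy as np
import pytest

from tdmbayes import PatientCovariates


@pytest.fixture
def typical_cov():
    """The 50-year-old 65 kg male used in worked examples."""
    return PatientCovariates(weight=65.1, height=165.1, age=50.2, sex="male",
                             scr=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
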