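import logging

import numpy as np
import pytest

from fggap.synthetic import GeneratorParams

logging.getLogger("fggap").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_params():
    return GeneratorParams()


@pytest.fixture
def clean_params():
    """Exact-recovery configuration: anchor letters excluded from background."""
    return GeneratorParams(clean_background=True, ca_motif_rate=0.0)
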