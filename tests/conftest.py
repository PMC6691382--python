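import logging

import numpy as np
import pytest

from mirisk.simulate import worked_toy

# module-level warning noise (skipped probes, consensus conflicts) is part of
# the contracts under test; keep it out of test output
logging.getLogger("mirisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy():
    """The hand-auditable worked dataset plus its frozen expectations."""
    return worked_toy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
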