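import numpy as np
import pytest

from dbtnet.model import DualNet, DualNetConfig
from dbtnet.synthdata import PhantomSpec, generate_phantom

TINY_CONFIG = DualNetConfig(shallow="tinycnn-shallow", deep="tinycnn-deep",
                            proj_dim=8, seed=0)


@pytest.fixture
def tiny_dualnet() -> DualNet:
    return DualNet(TINY_CONFIG)


@pytest.fixture(scope="session")
def phantom100():
    """The default-condition phantom study set (100 patients, fixed seed),
    shared across the synthetic-data and end-to-end tests."""
    return generate_phantom(PhantomSpec(seed=0))
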