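import numpy as np
import pytest

from idcmod.field import DiskSource, TissueModel, disk_field
from idcmod.rods import default_morphology


@pytest.fixture(scope="session")
def anodic_field():
    """Default-geometry field at +20 uA (shared; fields are expensive)."""
    return disk_field(TissueModel(), DiskSource(current=20e-6))


@pytest.fixture(scope="session")
def morphology():
    return default_morphology()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
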