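import numpy as np
import pytest

from franzperm import DoseSpec, FranzCellSpec, reference


@pytest.fixture
def cell():
    """Study-protocol Franz cell: 3 mL / 0.2 mL / 1.86 cm², 5 samples."""
    return FranzCellSpec()


@pytest.fixture
def dose():
    """300 µL of a 1% w/v donor solution (3,000 µg at 10,000 µg/mL)."""
    return DoseSpec()


@pytest.fixture
def tmwl_panel():
    """The bundled two-membrane 16-formulation TMWL panel."""
    return reference.load_tmwl_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20230905)
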