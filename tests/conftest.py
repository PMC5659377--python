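import numpy as np
import pytest

from dynclamp import MembraneParams

#: fitted lumped parameters of the reference model cell used throughout
R_M = 507.7  # MΩ
C_M = 35.9  # pF


@pytest.fixture(scope="session")
def model_cell() -> MembraneParams:
    return MembraneParams(R_m=R_M, C_m=C_M, E_rest=-70.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
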