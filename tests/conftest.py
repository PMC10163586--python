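import numpy as np
import pytest

from animfa import ModelParameters, builtin_pair


@pytest.fixture
def params_super():
    """Supercritical study conditions: tau=3, zeta=xi=1 (omega=1)."""
    return ModelParameters(tau=3.0, zeta=1.0, xi=1.0)


@pytest.fixture
def params_sub():
    """Subcritical conditions: tau=0.8, zeta=xi=1."""
    return ModelParameters(tau=0.8, zeta=1.0, xi=1.0)


@pytest.fixture(params=["rlad", "linear_breaking", "asis", "aid"])
def any_pair(request):
    return builtin_pair(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(20230506)
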