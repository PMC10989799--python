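import numpy as np
import pytest

from mdolsim import ModelParams
from mdolsim import pipelines


@pytest.fixture(scope="session")
def rep_notox():
    """Representative parameter set with toxicity disabled."""
    return ModelParams(toxicity_form="none", theta=0.0)


@pytest.fixture(scope="session")
def eq1_curve():
    """Representative-case df(s0) curve and its eq1 fit (shared, ~2 s)."""
    return pipelines.eq1_pipeline()


@pytest.fixture(scope="session")
def eq2_surface():
    """Representative-case df(s0, theta) surface and eq2 fit (~30 s)."""
    return pipelines.eq2_pipeline()


@pytest.fixture(scope="session")
def key_param_sweep():
    """Reduced no-toxicity sweep over the five key parameters with
    per-set eq1 fits (the heavyweight shared computation)."""
    return pipelines.key_parameter_fdmax_sweep()


@pytest.fixture(scope="session")
def ib_sweep_table():
    """Reduced colony sweep: 8 s0 x 3 theta x 3 seeds."""
    return pipelines.ib_sweep()
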