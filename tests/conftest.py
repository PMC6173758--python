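import numpy as np
import pytest

from isimodels import (
    ExpExcitation,
    ISISequence,
    RefractoryParams,
    RenewalModel,
    TwoExpMixExcitation,
    sample_isis,
)


@pytest.fixture(scope="session")
def exp_isis():
    """10^5 exponential ISIs, mean 20 ms (rate 0.05/ms)."""
    rng = np.random.default_rng(5)
    return ISISequence(rng.exponential(20.0, size=100_000))


@pytest.fixture(scope="session")
def case_i_model():
    return RenewalModel(RefractoryParams(t_abs=2.0, tau_rel=2.0), ExpExcitation(0.05))


@pytest.fixture(scope="session")
def case_iii_model():
    return RenewalModel(
        RefractoryParams(t_abs=2.0, tau_rel=2.0),
        TwoExpMixExcitation(p=0.6, lambda_e1=0.025, lambda_e2=0.005),
    )


@pytest.fixture(scope="session")
def case_iii_sample(case_iii_model):
    return ISISequence(sample_isis(case_iii_model, 5000, seed=12))
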