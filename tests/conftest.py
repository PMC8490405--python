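import numpy as np
import pytest

from ardca import TrainingConfig, fit
from ardca import fixtures as fx


@pytest.fixture(scope="session")
def small_truth():
    """Ground-truth autoregressive model, L=6, q=3, all pairs coupled."""
    spec = fx.FixtureSpec(L=6, q=3, M=0, seed=101, field_scale=0.6,
                          coupling_scale=0.4)
    return fx.random_armodel(spec, shuffle_order=True)


@pytest.fixture(scope="session")
def small_sample(small_truth):
    return small_truth.sample(4000, seed=102)


@pytest.fixture(scope="session")
def small_fit(small_truth, small_sample):
    """Model refit on a sample from small_truth using the truth's order."""
    cfg = TrainingConfig.preset("generative", order=small_truth.order,
                                theta=None)
    model, report = fit(small_sample, cfg)
    return model, report


@pytest.fixture(scope="session")
def profile_armodel():
    """An independent-site (J = 0) model as an ARModel, L=5, q=4."""
    rng = np.random.default_rng(103)
    from ardca.family import ProfileModel
    from ardca.msa import toy_alphabet
    f = rng.dirichlet(np.ones(4) * 2.0, size=5)
    return ProfileModel(f=f, alphabet=toy_alphabet(4))
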