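import numpy as np
import pytest

import limbmorph as lm
from limbmorph.synthetic import EvolParams, TraitParams, simulate_lnsize


@pytest.fixture(scope="session")
def study_tree():
    """76-tip ultrametric tree matching the study scale."""
    return lm.simulate_phylogeny(76, 2024)


@pytest.fixture(scope="session")
def study_ecotypes(study_tree):
    return lm.assign_clustered_ecotypes(study_tree, seed=2024)


@pytest.fixture(scope="session")
def small_tree():
    return lm.simulate_phylogeny(20, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trait_params(levels, beta1, sigma2=1.0, lam=0.0, beta0=None):
    beta0 = beta0 or {l: 10.0 for l in levels}
    return EvolParams(
        trait_params={"y": TraitParams(beta0=beta0, beta1=beta1,
                                       sigma2=sigma2, lam=lam)},
        size_sigma2=0.3, seed=0)
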