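import numpy as np
import pytest

import hfmcmc as h


@pytest.fixture(scope="session")
def toy():
    return h.get_model("toy")


@pytest.fixture(scope="session")
def truth():
    return h.toy_reference_params()


@pytest.fixture(scope="session")
def fixture2d():
    return h.get_model("bistable2d")


@pytest.fixture(scope="session")
def hists_weak_noise():
    """Generated fitness histograms at the weak-noise setting (variance 0.01)."""
    spec = h.GeneratorSpec(noise_variance=0.01, seed=7)
    return h.generate_fitness_histograms(spec)


@pytest.fixture(scope="session")
def full_problem(hists_weak_noise):
    return h.toy_problem(("B", "I", "T_e", "Y_end"), hists_weak_noise)


@pytest.fixture(scope="session")
def short_trace(full_problem):
    """A short full-fitness chain shared by sampler/posterior tests."""
    cfg = h.MCMCConfig(n_steps=20_000, burn_in=2_000, thin=3, sigma_q=0.5, seed=11)
    return h.run_mcmc_hfm(full_problem, cfg)


def linear_params(k_d=1.0, k_p=0.0, K=0.5):
    """Raw toy parameter mapping (allows k_p = 0, i.e. feedback disabled)."""
    return {"k_d": k_d, "k_p": k_p, "K": K}
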