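import numpy as np
import pytest

import methylseg as ms
from methylseg.hmm_segmentation import ObservationChain, chains_from_methylome


@pytest.fixture(scope="session")
def two_group_sim():
    """Small two-group cohort with 20 planted DMRs (10 samples)."""
    cfg = ms.two_group_dmr_config(n_dmrs=20, n_samples=10, seed=1)
    return ms.simulate_methylomes(cfg)


@pytest.fixture(scope="session")
def known_model_chain():
    """A 20k-site chain simulated from a known two-state model, plus truth."""
    rng = np.random.default_rng(123)
    A = np.array([[0.99, 0.01], [0.05, 0.95]])
    aH, bH, aL, bL = 6.0, 1.5, 0.5, 8.0
    T = 20_000
    states = np.empty(T, dtype=int)
    states[0] = 0
    u = rng.random(T)
    for t in range(1, T):
        stay = u[t] <= A[states[t - 1], states[t - 1]]
        states[t] = states[t - 1] if stay else 1 - states[t - 1]
    ctx = rng.integers(0, 3, T)
    n = rng.poisson(10, T) + 1
    p = np.where(states == 1, rng.beta(aH, bH, T), rng.beta(aL, bL, T))
    k = rng.binomial(n, p)
    chain = ObservationChain("chr", np.arange(T), k, n, ctx)
    truth = {
        "transition": A,
        "mean_high": aH / (aH + bH),
        "mean_low": aL / (aL + bL),
        "states": states,
    }
    return chain, truth


@pytest.fixture(scope="session")
def trained_sample(two_group_sim):
    """One sample's methylome with its trained segmentation model."""
    meth = two_group_sim.methylomes["sample01"]
    result = ms.baum_welch(chains_from_methylome(meth))
    return meth, result
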