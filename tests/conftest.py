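import numpy as np
import pytest

from memc import (
    EnergyFunction,
    FeatureMonomial,
    build_model,
    standard_feature_sets,
)

# canonical example features for a 2-neuron population
F_LAG_21 = FeatureMonomial(((0, 1), (1, 0)))  # neuron 1 at t, neuron 0 at t+1
F_LAG_12 = FeatureMonomial(((0, 0), (1, 1)))  # neuron 0 at t, neuron 1 at t+1
F_SYNC = FeatureMonomial(((0, 0), (0, 1)))  # synchronous pair
F_RATE0 = FeatureMonomial(((0, 0),))


@pytest.fixture(scope="session")
def lagged_pair_model():
    """Two-neuron range-two chain driven by a single lagged-pair feature
    (coefficient 1); Perron eigenvalue has the closed form e^beta + 3."""
    return build_model(EnergyFunction((F_LAG_21,), (1.0,), 2))


def make_lagged_pair_model(beta1: float):
    return build_model(EnergyFunction((F_LAG_21,), (float(beta1),), 2))


@pytest.fixture(scope="session")
def memory_model():
    """Two-neuron range-two chain with two lagged couplings and a
    synchronous coupling, beta = (-3, 3, 0.5); strongly irreversible."""
    return build_model(EnergyFunction((F_LAG_12, F_LAG_21, F_SYNC), (-3.0, 3.0, 0.5), 2))


@pytest.fixture(scope="session")
def memoryless_model():
    """Range-one chain for two neurons constrained only by the
    synchronous-pair average of the memory model (0.292611)."""
    from memc import fit

    _, model = fit([F_SYNC], [0.292611], 2)
    return model


@pytest.fixture(scope="session")
def bernoulli_quarter_model():
    """Single neuron firing i.i.d. with rate 0.25."""
    return build_model(EnergyFunction((F_RATE0,), (float(np.log(1 / 3)),), 1))


def random_memory_model(rng, n_neurons=2, scale=1.5):
    """Random two-lag + synchronous energy for property sweeps (range 2)."""
    feats = [
        FeatureMonomial(((0, 0), (1, min(1, n_neurons - 1)))),
        FeatureMonomial(((0, min(1, n_neurons - 1)), (1, 0))),
        FeatureMonomial(tuple((0, i) for i in range(min(2, n_neurons)))),
    ]
    # dedupe in the single-neuron case
    uniq = list(dict.fromkeys(feats))
    beta = rng.uniform(-scale, scale, size=len(uniq))
    return build_model(EnergyFunction(tuple(uniq), tuple(beta), n_neurons))


def random_iid_model(rng, n_neurons=2, scale=1.5):
    feats = standard_feature_sets("ising", n_neurons)
    beta = rng.uniform(-scale, scale, size=len(feats))
    return build_model(EnergyFunction(tuple(feats), tuple(beta), n_neurons))
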