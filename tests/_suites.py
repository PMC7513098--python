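"""Heavier randomized property sweeps shared between module tests and the
full-scale acceptance run (kept here so each can invoke them at its own
problem size)."""

import numpy as np

from memc import (
    EnergyFunction,
    FeatureMonomial,
    MarkovModel,
    SampleSpec,
    build_model,
    fit_from_raster,
    gc_symmetry_check,
    ep_scgf_and_rate,
    ks_entropy,
    model_expectation,
    pressure_hessian,
    sample,
    scgf_value,
)

RECOVERY_FEATURES = (
    FeatureMonomial(((0, 0), (1, 1))),
    FeatureMonomial(((0, 1), (1, 0))),
    FeatureMonomial(((0, 0), (0, 1))),
)


def parameter_recovery_successes(n_replicates: int, T: int, seed: int) -> int:
    """Sample each replicate's ground-truth chain, refit from the raster,
    and count replicates whose every coefficient lands within 3 estimated
    standard errors (delta method: Cov(beta_hat) ~ L^-1 / T)."""
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_replicates):
        beta = rng.uniform(-2, 2, size=len(RECOVERY_FEATURES))
        truth = build_model(EnergyFunction(RECOVERY_FEATURES, tuple(beta), 2))
        raster = sample(truth, SampleSpec(length=T, seed=int(rng.integers(2**31))))
        result, _ = fit_from_raster(raster, RECOVERY_FEATURES)
        L = pressure_hessian(truth, richardson=False).L
        se = np.sqrt(np.diag(np.linalg.inv(L)) / T)
        if np.all(np.abs(result.beta - beta) <= 3 * se):
            successes += 1
    return successes


def variational_gaps(model: MarkovModel, n_perturbations: int, seed: int, strength: float = 0.5):
    """P[H] - (S_KS(q) + E_q[H]) for randomly perturbed stochastic
    matrices q sharing P's support; all gaps must be >= 0 with equality
    only at the MEMC itself."""
    rng = np.random.default_rng(seed)
    P = model.P
    energy = model.energy
    gaps = []
    h_matrix = _energy_transition_matrix(model)
    for _ in range(n_perturbations):
        noise = rng.uniform(1 - strength, 1 + strength, size=P.shape)
        Q = np.where(P > 0, P * noise, 0.0)
        Q = Q / Q.sum(axis=1, keepdims=True)
        piq = _stationary(Q)
        s_q = -(piq @ np.where(Q > 0, Q * np.log(np.where(Q > 0, Q, 1.0)), 0.0).sum(axis=1))
        e_q = float(piq @ (Q * h_matrix).sum(axis=1))
        gaps.append(model.pressure - (s_q + e_q))
    return np.asarray(gaps)


def _energy_transition_matrix(model: MarkovModel) -> np.ndarray:
    from memc.chain import transition_observable_matrix

    return transition_observable_matrix(model, lambda block: model.energy.evaluate(block))


def _stationary(Q: np.ndarray) -> np.ndarray:
    w, vl = np.linalg.eig(Q.T)
    i = int(np.argmax(w.real))
    v = np.abs(vl[:, i].real)
    return v / v.sum()


def path_oracle_gaps(model: MarkovModel, observable, k: float, lengths=(4, 6, 8)):
    """|oracle - spectral| where the oracle evaluates
    (1/t) ln E[e^{k t A_t(f)}] by explicit enumeration of every pattern
    path of length t; the gap must shrink as t grows."""
    lam = scgf_value(model, observable, k)
    gaps = []
    for t in lengths:
        gaps.append(abs(_enumerated_scgf(model, observable, k, t) - lam))
    return np.asarray(gaps)


def _enumerated_scgf(model: MarkovModel, observable, k: float, t: int) -> float:
    """Brute-force finite-t generating function over all 2^(N t) paths."""
    space = model.state_space
    N = space.n_neurons
    R = model.range
    assert R == 2 and N <= 2, "oracle sized for tiny chains"
    n_pat = space.n_patterns
    total = 0.0
    pats = [space.pattern_array(q) for q in range(n_pat)]
    import itertools

    for path in itertools.product(range(n_pat), repeat=t):
        prob = model.pi[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            prob *= model.P[a, b]
        if prob == 0.0:
            continue
        blocks = [np.vstack([pats[a], pats[b]]) for a, b in zip(path[:-1], path[1:])]
        avg = float(np.mean([observable(blk) for blk in blocks]))
        total += prob * np.exp(k * t * avg)
    return float(np.log(total) / t)


def gc_asymmetries(n_models: int, seed: int) -> np.ndarray:
    """Gallavotti-Cohen asymmetry of lambda_W over randomized two-neuron
    range-two chains."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_models):
        beta = rng.uniform(-2, 2, size=len(RECOVERY_FEATURES))
        model = build_model(EnergyFunction(RECOVERY_FEATURES, tuple(beta), 2))
        curve = ep_scgf_and_rate(model, np.linspace(-1.4, 0.4, 41))
        out.append(gc_symmetry_check(curve))
    return np.asarray(out)
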