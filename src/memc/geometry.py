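"""Information geometry of maximum-entropy Markov chains.

The relative entropy density between Gibbs-type Markov measures is
expressible through the pressure (Ruelle-Foellmer):

    d(q|p) = P[H_p] - S_KS(q) - E_q{H_p},

non-negative and zero iff q is p's MEMC.  When q is itself a MEMC over
the same features, substituting its own variational equality gives the
pure pressure form d(q|p) = P[H_p] - P[H_q] + E_q{H_q} - E_q{H_p}.

The Hessian L of the pressure in beta is the asymptotic covariance matrix
of the feature averages (a Fisher-information analogue).  Two models
differing by delta_beta are epsilon-indistinguishable from T samples when
(1/2) delta_beta' L delta_beta <= epsilon / T; the set of such
perturbations is an ellipsoid whose volume follows from L's spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gamma, pi as PI

import numpy as np

from .chain import (
    MarkovModel,
    build_model,
    ks_entropy,
    model_expectation,
)

__all__ = [
    "Hessian",
    "relative_entropy",
    "pressure_hessian",
    "indistinguishability",
    "indistinguishable_volume",
]


@dataclass
class Hessian:
    """Symmetric positive-semidefinite pressure Hessian with spectrum."""

    L: np.ndarray
    eigenvalues: np.ndarray


def _energy_expectation(q: MarkovModel, energy) -> float:
    """E_q{H} for an energy of range <= q's range."""
    Rq = q.range
    R = energy.range
    if R > Rq:
        raise ValueError(
            f"energy range {R} exceeds the chain's range {Rq}: state spaces differ"
        )
    return model_expectation(q, lambda block: energy.evaluate(block[:R]))


def relative_entropy(p: MarkovModel, q: MarkovModel, method: str = "variational") -> float:
    """Relative entropy density d(q|p) >= 0.

    method="variational"
        P[H_p] - S_KS(q) - E_q{H_p}; valid for any ergodic chain q on
        p's state space.
    method="pressure"
        P[H_p] - P[H_q] + E_q{H_q} - E_q{H_p}; valid when q is itself a
        MEMC (uses q's own variational equality).  The two routes agree
        to numerical precision for MEMC pairs.
    """
    if p.state_space.n_neurons != q.state_space.n_neurons or p.state_space.word_length != q.state_space.word_length:
        raise ValueError("models live on different state spaces")
    if method == "variational":
        val = p.pressure - ks_entropy(q) - _energy_expectation(q, p.energy)
    elif method == "pressure":
        val = (
            p.pressure
            - q.pressure
            + _energy_expectation(q, q.energy)
            - _energy_expectation(q, p.energy)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(val)


def pressure_hessian(model: MarkovModel, h: float = 1e-4, richardson: bool = True) -> Hessian:
    """K x K matrix of second derivatives of the pressure in beta, by
    Richardson-extrapolated central differences; symmetrized by averaging
    with its transpose.  For a range-one single-feature model L_11 is the
    stationary variance of the feature."""
    energy = model.energy
    beta = energy.beta
    K = len(beta)
    rep = model.transfer.representation

    def pr(b: np.ndarray) -> float:
        return build_model(energy.with_coefficients(b), rep).pressure

    def hess_at(step: float) -> np.ndarray:
        L = np.empty((K, K))
        p0 = model.pressure
        for k in range(K):
            ek = np.zeros(K)
            ek[k] = step
            L[k, k] = (pr(beta + ek) - 2 * p0 + pr(beta - ek)) / step**2
            for j in range(k + 1, K):
                ej = np.zeros(K)
                ej[j] = step
                L[k, j] = L[j, k] = (
                    pr(beta + ek + ej)
                    - pr(beta + ek - ej)
                    - pr(beta - ek + ej)
                    + pr(beta - ek - ej)
                ) / (4 * step**2)
        return L

    L = hess_at(h)
    if richardson:
        L = (4 * hess_at(h / 2) - L) / 3
    L = 0.5 * (L + L.T)
    eigs = np.linalg.eigvalsh(L)
    if eigs.min() < -1e-6 * max(1.0, eigs.max()):
        warnings.warn(
            f"pressure Hessian has a negative eigenvalue {eigs.min():.3e}; "
            "finite differencing may be ill-conditioned",
            RuntimeWarning,
        )
    return Hessian(L, eigs)


def indistinguishability(
    model: MarkovModel, delta_beta, epsilon: float, T: int, hessian: Hessian | None = None
) -> tuple[bool, float]:
    """Quadratic-form test: s = (1/2) delta_beta' L delta_beta against
    epsilon / T.  Returns (indistinguishable, statistic); the statistic
    approximates d(p|p') to second order in delta_beta."""
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    if not T >= 1:
        raise ValueError("T must be >= 1")
    db = np.asarray(delta_beta, float)
    if db.shape != (len(model.energy.coefficients),):
        raise ValueError("delta_beta dimension does not match the model's beta")
    L = (hessian or pressure_hessian(model)).L
    s = float(0.5 * db @ L @ db)
    return s <= epsilon / T, s


def indistinguishable_volume(
    model: MarkovModel, epsilon: float, T: int, hessian: Hessian | None = None
):
    """Volume of the ellipsoid {delta_beta : (1/2) db' L db <= eps/T}:
    V_K * prod_k sqrt(2 eps / (T lambda_k)), V_K the unit-ball volume.

    Returns (volume, null_basis); a singular L yields infinite volume
    along its null directions, reported via the basis.
    """
    hess = hessian or pressure_hessian(model)
    eigs, vecs = np.linalg.eigh(hess.L)
    K = len(eigs)
    tol = 1e-10 * max(1.0, float(np.abs(eigs).max()))
    null = eigs <= tol
    if null.any():
        return float("inf"), vecs[:, null]
    unit_ball = PI ** (K / 2) / gamma(K / 2 + 1)
    vol = unit_ball * float(np.prod(np.sqrt(2 * epsilon / (T * eigs))))
    return vol, None
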