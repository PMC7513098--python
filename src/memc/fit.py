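"""Maximum-entropy parameter inference.

Matching model expectations to empirical constraints is a smooth convex
dual problem: minimize F(beta) = P[H_beta] - sum_k beta_k c_k, whose
gradient is E_p{f_k} - c_k (pressure derivatives are stationary feature
expectations).  At the optimum the model reproduces every constraint and
is the entropy-rate maximizer among chains doing so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .chain import (
    MarkovModel,
    StateSpace,
    build_model,
    model_expectation,
)
from .features import EnergyFunction, FeatureMonomial
from .raster import SpikeRaster, empirical_average

__all__ = ["FitResult", "fit", "fit_from_raster"]

#: constraint-matching tolerance declared at convergence
DEFAULT_TOL = 1e-8
#: constraints closer than this to 0/1 trigger a looser tolerance
BOUNDARY_MARGIN = 1e-6


@dataclass
class FitResult:
    beta: np.ndarray
    constraints: np.ndarray
    achieved: np.ndarray
    gradient_norm: float
    iterations: int
    converged: bool


def _feature_value_table(features, n_neurons: int) -> np.ndarray:
    """(n_blocks x K) evaluation of every feature over all R-blocks."""
    R = max(f.range for f in features)
    bspace = StateSpace(n_neurons, R)
    tab = np.empty((bspace.n_states, len(features)))
    for b in range(bspace.n_states):
        block = bspace.decode(b)
        for k, f in enumerate(features):
            tab[b, k] = f.evaluate(block)
    return tab


def fit(
    features,
    constraints,
    n_neurons: int,
    *,
    tol: float = DEFAULT_TOL,
    max_iterations: int = 500,
    beta0=None,
    representation: str = "memory",
) -> tuple[FitResult, MarkovModel]:
    """Infer beta such that the MEMC reproduces the target averages.

    Parameters
    ----------
    features
        K monomial features (linearly independent over blocks).
    constraints
        Target averages c_k, each strictly inside (0, 1).
    n_neurons
        Population size N.

    Returns the fit report and the fitted model.  Raises on boundary
    constraints (beta diverges) and on duplicate features; warns and
    loosens the tolerance for constraints within 1e-6 of the boundary.
    """
    features = tuple(features)
    c = np.asarray(constraints, dtype=float)
    if c.shape != (len(features),):
        raise ValueError("one constraint per feature required")
    if ((c <= 0) | (c >= 1)).any():
        raise ValueError("boundary constraint: feature average at 0 or 1, beta diverges")
    if ((c < BOUNDARY_MARGIN) | (c > 1 - BOUNDARY_MARGIN)).any():
        warnings.warn(
            "constraint within 1e-6 of the boundary; convergence tolerance loosened",
            RuntimeWarning,
        )
        tol = max(tol, 1e-5)

    tab = _feature_value_table(features, n_neurons)
    _, idx = np.unique(tab, axis=1, return_index=True)
    if len(idx) != tab.shape[1]:
        dup = sorted(set(range(tab.shape[1])) - set(idx))
        raise ValueError(
            f"duplicate features (identical on every block): indices {dup}"
        )
    cond = np.linalg.cond(np.column_stack([tab, np.ones(len(tab))]))
    if cond > 1e10:
        warnings.warn(
            f"feature set nearly linearly dependent (condition number {cond:.2e})",
            RuntimeWarning,
        )

    x0 = np.zeros(len(features)) if beta0 is None else np.asarray(beta0, float)
    cache: dict = {}

    def model_at(beta: np.ndarray) -> MarkovModel:
        key = beta.tobytes()
        if key not in cache:
            cache.clear()
            energy = EnergyFunction(features, tuple(beta), n_neurons)
            cache[key] = build_model(energy, representation)
        return cache[key]

    def objective(beta):
        model = model_at(beta)
        val = model.pressure - beta @ c
        grad = np.array([model_expectation(model, f) for f in features]) - c
        return val, grad

    res = minimize(
        objective,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": tol * 1e-2, "maxiter": max_iterations},
    )
    model = model_at(res.x)
    achieved = np.array([model_expectation(model, f) for f in features])
    gap = float(np.abs(achieved - c).max())
    result = FitResult(
        beta=res.x.copy(),
        constraints=c,
        achieved=achieved,
        gradient_norm=gap,
        iterations=int(res.nit),
        converged=gap <= tol,
    )
    if not result.converged:
        warnings.warn(
            f"fit did not reach tolerance: max |E[f]-c| = {gap:.3e} "
            f"after {res.nit} iterations",
            RuntimeWarning,
        )
    return result, model


def fit_from_raster(
    raster: SpikeRaster, features, **options
) -> tuple[FitResult, MarkovModel]:
    """Compute empirical averages of the features over the raster, then fit."""
    features = tuple(features)
    c = np.array([empirical_average(raster, f) for f in features])
    return fit(features, c, raster.n_neurons, **options)
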