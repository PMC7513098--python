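"""Large-deviation analysis of time-averaged observables.

For an ergodic chain P with invariant measure pi and a block observable f,
the scaled cumulant generating function (SCGF) of the time-average A_t(f)
is the log Perron eigenvalue of the tilted matrix

    Ptilde_ij(k) = P_ij * exp(k * f(b_ij)),

where b_ij is the spike block realized by the transition i -> j
(Gaertner-Ellis route).  The rate function I_f(s) is its Legendre
transform; probabilities of atypical averages decay like exp(-t I_f(s)).
Derivatives of the SCGF at k = 0 give the stationary cumulants: mean,
asymptotic variance (the CLT sigma^2), and so on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .chain import MarkovModel, transition_observable_matrix

__all__ = [
    "LDCurve",
    "tilted_matrix",
    "scgf_value",
    "scgf",
    "legendre",
    "ld_curve",
    "cumulants",
    "asymptotic_variance",
    "fluctuation_overlay",
]

DEFAULT_K_GRID = np.linspace(-5.0, 5.0, 401)


@dataclass
class LDCurve:
    """Paired SCGF and rate-function grids for one observable.

    ``s_star`` is the rate function's zero (the stationary mean) and
    ``sigma2 = lambda''(0)`` the asymptotic variance of the CLT.
    Grid points whose slope target is unattainable carry ``rate = inf``.
    """

    k_grid: np.ndarray
    scgf: np.ndarray
    s_grid: np.ndarray
    rate: np.ndarray
    s_star: float
    sigma2: float


def _spectral_radius(M: np.ndarray) -> float:
    w = np.linalg.eigvals(M)
    return float(w.real.max())


def tilted_matrix(model: MarkovModel, observable, k: float) -> np.ndarray:
    """Ptilde(k) = P * exp(k f) entry-wise along transitions; equals P at
    k = 0.  ``observable`` is a FeatureMonomial of range <= R or any
    callable on time-major (R, N) blocks."""
    O = transition_observable_matrix(model, observable)
    return model.P * np.exp(float(k) * O)


def _scgf_from_obs(model: MarkovModel, O: np.ndarray, k: float) -> float:
    """ln rho of the tilted matrix, overflow-safe: the observable is
    shifted so the largest tilt exponent is zero and the shift restored
    additively (lambda(k) = k*c + ln rho(P e^{k(f-c)}))."""
    mask = model.P > 0
    vals = O[mask]
    shift = float(vals.max()) if k >= 0 else float(vals.min())
    M = model.P * np.where(mask, np.exp(k * (O - shift)), 0.0)
    rho = _spectral_radius(M)
    if not rho > 0:
        raise OverflowError(f"tilted matrix degenerate at k={k}")
    return k * shift + float(np.log(rho))


def scgf_value(model: MarkovModel, observable, k: float) -> float:
    """lambda_f(k), the SCGF at a single k."""
    O = transition_observable_matrix(model, observable)
    return _scgf_from_obs(model, O, float(k))


def scgf(model: MarkovModel, observable, k_grid=None) -> np.ndarray:
    """lambda_f on a grid of k values (overflowing points yield NaN with
    a warning)."""
    k_grid = DEFAULT_K_GRID if k_grid is None else np.asarray(k_grid, float)
    O = transition_observable_matrix(model, observable)
    out = np.empty_like(k_grid)
    for i, k in enumerate(k_grid):
        try:
            out[i] = _scgf_from_obs(model, O, k)
        except (OverflowError, FloatingPointError):
            warnings.warn(f"SCGF overflow at k={k}; grid point dropped", RuntimeWarning)
            out[i] = np.nan
    return out


def legendre(k_grid, scgf_values, s_grid=None, n_s: int = 201):
    """Legendre transform I(s) = max_k {k s - lambda(k)} from a sampled
    SCGF curve: grid maximization refined by bounded scalar optimization
    on a cubic interpolant (ties broken toward smaller |k|).

    Returns (s_grid, rate).  By default s spans the slope range observed
    on the k-grid; requested s outside it get rate = +inf.
    """
    from scipy.interpolate import CubicSpline

    k = np.asarray(k_grid, float)
    lam = np.asarray(scgf_values, float)
    good = np.isfinite(lam)
    k, lam = k[good], lam[good]
    if len(k) < 4:
        raise ValueError("too few finite SCGF points for a Legendre transform")
    spline = CubicSpline(k, lam)
    slopes = spline(k, 1)
    lo, hi = float(slopes.min()), float(slopes.max())
    if s_grid is None:
        pad = 1e-6 * max(1.0, hi - lo)
        s_grid = np.linspace(lo + pad, hi - pad, n_s)
    else:
        s_grid = np.asarray(s_grid, float)

    rate = np.empty_like(s_grid)
    for i, s in enumerate(s_grid):
        if s < lo or s > hi:
            rate[i] = np.inf
            continue
        g = k * s - lam
        order = np.lexsort((np.abs(k), -g))  # best g first, smaller |k| on ties
        j = order[0]
        a, b = k[max(j - 1, 0)], k[min(j + 1, len(k) - 1)]
        if a == b:
            rate[i] = g[j]
            continue
        res = minimize_scalar(
            lambda x: -(x * s - float(spline(x))),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-12},
        )
        rate[i] = max(-res.fun, g[j])
    return s_grid, rate


def ld_curve(model: MarkovModel, observable, k_grid=None, s_grid=None, n_s: int = 201) -> LDCurve:
    """Full large-deviation curve for an observable.

    The rate function is computed by maximizing k*s - lambda(k) with
    exact spectral evaluations of lambda (grid bracketing plus bounded
    refinement), which keeps the transform accurate to the eigensolver
    tolerance rather than the grid resolution.
    """
    k = DEFAULT_K_GRID if k_grid is None else np.asarray(k_grid, float)
    O = transition_observable_matrix(model, observable)

    def lam(x: float) -> float:
        return _scgf_from_obs(model, O, x)

    lam_grid = np.array([lam(x) for x in k])
    slopes = np.gradient(lam_grid, k)
    lo, hi = float(slopes.min()), float(slopes.max())
    if s_grid is None:
        pad = 1e-4 * max(1.0, hi - lo)
        s_grid = np.linspace(lo + pad, hi - pad, n_s)
    else:
        s_grid = np.asarray(s_grid, float)

    rate = np.empty_like(s_grid)
    for i, s in enumerate(s_grid):
        if s < lo or s > hi:
            rate[i] = np.inf
            continue
        g = k * s - lam_grid
        j = int(np.argmax(g))
        a, b = k[max(j - 1, 0)], k[min(j + 1, len(k) - 1)]
        res = minimize_scalar(
            lambda x: -(x * s - lam(x)),
            bounds=(float(a), float(b)),
            method="bounded",
            options={"xatol": 1e-11},
        )
        rate[i] = max(float(-res.fun), float(g[j]), 0.0)

    kappa = cumulants(model, observable, order=2)
    return LDCurve(k, lam_grid, s_grid, rate, s_star=kappa[0], sigma2=kappa[1])


# step sizes balance truncation against eigensolver round-off amplified
# by 1/h^n; Richardson extrapolation keeps the truncation term negligible
_RICHARDSON_STEPS = {1: 1e-4, 2: 1e-3, 3: 2e-2, 4: 5e-2}


def cumulants(model: MarkovModel, observable, order: int = 4, h: float | None = None) -> np.ndarray:
    """First ``order`` cumulants of the time-averaged observable, from
    Richardson-extrapolated central differences of the SCGF at 0.

    kappa_1 is the stationary mean, kappa_2 the asymptotic variance.
    Higher orders divide tiny eigenvalue differences by h^3, h^4 and are
    the accuracy bottleneck; larger default steps are used there.
    """
    if order not in (1, 2, 3, 4):
        raise ValueError("order must be in 1..4")
    O = transition_observable_matrix(model, observable)

    def lam(x: float) -> float:
        return 0.0 if x == 0.0 else _scgf_from_obs(model, O, x)

    def stencil(n: int, step: float) -> float:
        if n == 1:
            return (lam(step) - lam(-step)) / (2 * step)
        if n == 2:
            return (lam(step) - 2 * lam(0.0) + lam(-step)) / step**2
        if n == 3:
            return (lam(2 * step) - 2 * lam(step) + 2 * lam(-step) - lam(-2 * step)) / (
                2 * step**3
            )
        return (
            lam(2 * step) - 4 * lam(step) + 6 * lam(0.0) - 4 * lam(-step) + lam(-2 * step)
        ) / step**4

    out = np.empty(order)
    for n in range(1, order + 1):
        step = h if h is not None else _RICHARDSON_STEPS[n]
        d1, d2 = stencil(n, step), stencil(n, step / 2)
        if abs(d1 - d2) > 10 * max(abs(d1), abs(d2), 1e-12):
            warnings.warn(
                f"cumulant order {n}: finite-difference step degeneracy", RuntimeWarning
            )
        out[n - 1] = (4 * d2 - d1) / 3
    return out


def asymptotic_variance(model: MarkovModel, observable, observable2=None) -> float:
    """lambda''(0): the variance constant of the CLT for time-averages.

    With a second observable, returns the asymptotic *covariance* via the
    polarization identity on the SCGF of f+g.
    """
    if observable2 is None:
        return float(cumulants(model, observable, order=2)[1])
    Oa = transition_observable_matrix(model, observable)
    Ob = transition_observable_matrix(model, observable2)

    # polarization: cov = (var(f+g) - var(f) - var(g)) / 2
    def k2(O):
        h = _RICHARDSON_STEPS[2]

        def lam(x):
            return 0.0 if x == 0.0 else _scgf_from_obs(model, O, x)

        def d2(step):
            return (lam(step) + lam(-step)) / step**2

        return (4 * d2(h / 2) - d2(h)) / 3

    return float((k2(Oa + Ob) - k2(Oa) - k2(Ob)) / 2)


def fluctuation_overlay(
    model: MarkovModel,
    observable,
    window: int,
    s_grid,
    mass: float = 1.0,
    curve: LDCurve | None = None,
):
    """Predicted density of window-averages: K * exp(-W * I_f(s)).

    K is set so the curve's trapezoidal mass over ``s_grid`` equals
    ``mass`` (match it to a histogram's mass to overlay).  Returns
    (s_grid, density).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s_grid = np.asarray(s_grid, float)
    if curve is None:
        curve = ld_curve(model, observable, s_grid=s_grid)
        rate = curve.rate
    else:
        rate = np.interp(s_grid, curve.s_grid, curve.rate)
    y = np.where(np.isfinite(rate), np.exp(-window * np.where(np.isfinite(rate), rate, 0.0)), 0.0)
    total = np.trapezoid(y, s_grid)
    if total > 0:
        y = y * (mass / total)
    return s_grid, y
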