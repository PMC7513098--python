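"""Information entropy production and its fluctuation statistics.

A stationary chain is in equilibrium exactly when it satisfies detailed
balance, pi_i P_ij = pi_j P_ji.  The information entropy production (IEP)

    IEP = (1/2) sum_ij (pi_i P_ij - pi_j P_ji) ln(pi_i P_ij / pi_j P_ji)

is the asymptotic rate at which forward trajectories become more probable
than their time reversals; it is non-negative and vanishes iff detailed
balance holds.  Range-one (i.i.d.) chains are always reversible; range-two
energies generically are not.

Finite-time fluctuations of the path log-ratio W_t follow a large
deviation principle whose SCGF is the log Perron eigenvalue of

    F_ij(k) = P_ij * (pi_i P_ij / pi_j P_ji)^k,

and obeys the Gallavotti-Cohen symmetry lambda_W(k) = lambda_W(-1-k).

These formulas require every visited transition to have a positive
reverse, which holds structurally for chain memory <= 1 (energy range
R <= 2); for longer memories the reverse transitions have structural
zeros and the printed formula diverges, so the operations refuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import MarkovModel, detailed_balance_residual
from .ldp import LDCurve, _spectral_radius, legendre
from .raster import SpikeRaster

__all__ = [
    "EPReport",
    "iep",
    "ep_tilted_matrix",
    "ep_scgf_and_rate",
    "gc_symmetry_check",
    "wt_trajectory",
    "entropy_production_report",
]

DEFAULT_EP_K_GRID = np.linspace(-1.5, 0.5, 201)  # symmetric about k = -1/2


def _check_support(model: MarkovModel) -> None:
    if model.range > 2:
        raise ValueError(
            "time reversal with memory >= 2 has structural zeros in the "
            "reverse transitions; the pairwise entropy-production formula "
            "is not defined there (see docs/methods.md)"
        )
    flux = model.pi[:, None] * model.P
    if ((flux > 0) & (flux.T <= 0)).any():
        raise ValueError("a transition with zero reverse probability was found")


def iep(model: MarkovModel) -> float:
    """Information entropy production (nats/bin), >= 0; zero iff the
    chain satisfies detailed balance."""
    _check_support(model)
    flux = model.pi[:, None] * model.P
    mask = flux > 0
    ratio = np.ones_like(flux)
    ratio[mask] = flux[mask] / flux.T[mask]
    val = 0.5 * np.sum((flux - flux.T)[mask] * np.log(ratio[mask]))
    return float(max(val, 0.0))


def ep_tilted_matrix(model: MarkovModel, k: float) -> np.ndarray:
    """F(k) with entries P_ij (pi_i P_ij / pi_j P_ji)^k; F(0) = P."""
    _check_support(model)
    flux = model.pi[:, None] * model.P
    mask = flux > 0
    ratio = np.ones_like(flux)
    ratio[mask] = flux[mask] / flux.T[mask]
    return model.P * ratio**float(k)


def _lambda_w(model: MarkovModel, k: float) -> float:
    return float(np.log(_spectral_radius(ep_tilted_matrix(model, k))))


def ep_scgf_and_rate(model: MarkovModel, k_grid=None, n_s: int = 201) -> LDCurve:
    """SCGF lambda_W(k) = ln rho(F(k)) on a grid (default symmetric about
    -1/2) and the rate function I_W by Legendre transform."""
    k_grid = DEFAULT_EP_K_GRID if k_grid is None else np.asarray(k_grid, float)
    lam = np.array([_lambda_w(model, k) for k in k_grid])
    h = 1e-4
    mean_w = (_lambda_w(model, h) - _lambda_w(model, -h)) / (2 * h)
    sigma2 = (_lambda_w(model, h) + _lambda_w(model, -h)) / h**2
    if np.ptp(lam) < 1e-13:
        # detailed balance: lambda_W vanishes identically, I_W supported at 0
        s_grid = np.array([0.0])
        rate = np.array([0.0])
    else:
        s_grid, rate = legendre(k_grid, lam, n_s=n_s)
    return LDCurve(k_grid, lam, s_grid, rate, s_star=mean_w, sigma2=sigma2)


def gc_symmetry_check(curve: LDCurve) -> float:
    """Gallavotti-Cohen asymmetry max_k |lambda_W(k) - lambda_W(-1-k)|.

    Exact (reversal-based) when the k-grid is symmetric about -1/2,
    interpolated otherwise.
    """
    k, lam = curve.k_grid, curve.scgf
    mapped = -1.0 - k
    if np.allclose(mapped, k[::-1], atol=1e-12):
        return float(np.abs(lam - lam[::-1]).max())
    inside = (mapped >= k.min()) & (mapped <= k.max())
    lam_m = np.interp(mapped[inside], k, lam)
    return float(np.abs(lam[inside] - lam_m).max())


def wt_trajectory(model: MarkovModel, raster: SpikeRaster) -> np.ndarray:
    """Running path log-ratio W_t = (1/t) ln[p(x_{0,t-1}) / p(reversed)]
    for t = 1..T; converges to the IEP along samples of the model.

    The model's own stationary measure supplies the initial-state factor
    of both the forward and the reversed path.
    """
    _check_support(model)
    space = model.state_space
    N = space.n_neurons
    if raster.n_neurons != N:
        raise ValueError("raster population size does not match the model")
    bits = 1 << np.arange(N)
    pats = (raster.data.astype(np.int64).T * bits).sum(axis=1)
    T = len(pats)
    with np.errstate(divide="ignore"):
        lnP = np.where(model.P > 0, np.log(np.where(model.P > 0, model.P, 1.0)), -np.inf)
    lnpi = np.log(model.pi)

    w = np.zeros(T)
    if model.range == 1:
        return w  # i.i.d. chains: forward and reversed paths are equiprobable
    # memory 1: states are single patterns
    ln_fwd = lnpi[pats[0]]
    ln_rev = lnpi[pats[0]]
    for t in range(1, T):
        a, b = pats[t - 1], pats[t]
        step_f = lnP[a, b]
        step_r = lnP[b, a]
        if not np.isfinite(step_f) or not np.isfinite(step_r):
            raise ValueError(
                f"visited transition {a}->{b} has zero model probability"
            )
        ln_fwd += step_f
        # reversed prefix gains pattern b at its head:
        # p_rev(t+1) = pi(b) P(b->a) * p_rev(t) / pi(a)
        ln_rev = lnpi[b] + step_r + (ln_rev - lnpi[a])
        w[t] = (ln_fwd - ln_rev) / (t + 1)
    return w


@dataclass
class EPReport:
    """Summary of a chain's irreversibility: the IEP, the detailed-balance
    residual, the W-fluctuation curve, and the Gallavotti-Cohen asymmetry."""

    iep: float
    db_residual: float
    scgf_curve: LDCurve
    gc_max_asymmetry: float


def entropy_production_report(model: MarkovModel, k_grid=None) -> EPReport:
    curve = ep_scgf_and_rate(model, k_grid)
    return EPReport(
        iep=iep(model),
        db_residual=detailed_balance_residual(model),
        scgf_curve=curve,
        gc_max_asymmetry=gc_symmetry_check(curve),
    )
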