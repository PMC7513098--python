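"""Sampling spike rasters from a MEMC, and the memory-vs-memoryless
fluctuation comparison workflow.

The sampler draws the initial memory word from the invariant measure (the
chain starts exactly stationary, so no burn-in is needed by default) and
then walks the transition matrix by inverse-CDF draws on precomputed
cumulative rows; runs are fully reproducible from the integer seed, which
is recorded in the raster metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import MarkovModel
from .ldp import asymptotic_variance, fluctuation_overlay
from .raster import SpikeRaster, sliding_window_averages

__all__ = ["SampleSpec", "sample", "FluctuationExperiment", "fluctuation_experiment"]


@dataclass
class SampleSpec:
    """Length (in time bins), RNG seed, and optional burn-in steps."""

    length: int
    seed: int
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def sample(model: MarkovModel, spec: SampleSpec) -> SpikeRaster:
    """Draw a stationary trajectory of exactly ``spec.length`` spike
    patterns from the chain."""
    space = model.state_space
    N = space.n_neurons
    m = max(model.range - 1, 1)
    T = spec.length
    if T < m:
        raise ValueError(f"length {T} shorter than the model memory {m}")
    rng = np.random.default_rng(spec.seed)

    n_states, n_pat = space.n_states, space.n_patterns
    # per-state cumulative distribution over the 2^N successor patterns
    succ_prob = np.empty((n_states, n_pat))
    succ_state = np.empty((n_states, n_pat), dtype=np.int64)
    for s in range(n_states):
        for q in range(n_pat):
            j = space.successor(s, q)
            succ_state[s, q] = j
            succ_prob[s, q] = model.P[s, j]
    cum = np.cumsum(succ_prob, axis=1)
    cum[:, -1] = 1.0

    state = int(np.searchsorted(np.cumsum(model.pi), rng.random()))
    for _ in range(spec.burn_in):
        q = int(np.searchsorted(cum[state], rng.random()))
        state = int(succ_state[state, q])

    patterns = np.empty(T, dtype=np.int64)
    if model.range >= 2:
        # the initial word supplies the first m patterns
        word = state
        mask = n_pat - 1
        for k in range(m):
            patterns[k] = (word >> (N * k)) & mask
        start = m
    else:
        patterns[0] = int(np.searchsorted(cum[state], rng.random()))
        state = int(succ_state[state, patterns[0]])
        start = 1
    u = rng.random(T - start)
    cum_rows = cum  # local alias for the loop
    for t in range(start, T):
        q = int(np.searchsorted(cum_rows[state], u[t - start]))
        patterns[t] = q
        state = int(succ_state[state, q])

    bits = 1 << np.arange(N, dtype=np.int64)
    data = ((patterns[None, :] & bits[:, None]) > 0).astype(np.uint8)
    return SpikeRaster(
        data,
        bin_width=1.0,
        metadata={"seed": spec.seed, "burn_in": spec.burn_in, "generator": "pcg64"},
    )


@dataclass
class FluctuationExperiment:
    """Window-average histogram from the full model's sample, with the
    large-deviation overlays K exp(-W I(s)) predicted by both models."""

    window_averages: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    s_grid: np.ndarray
    overlay_full: np.ndarray
    overlay_reduced: np.ndarray
    var_full: float
    var_reduced: float


def fluctuation_experiment(
    model_full: MarkovModel,
    model_reduced: MarkovModel,
    observable,
    T: int,
    window: int,
    seed: int,
    n_bins: int = 25,
    n_s: int = 201,
) -> FluctuationExperiment:
    """Sample the full model, histogram disjoint window-averages of the
    observable, and overlay the fluctuation densities predicted by the
    full and the reduced (memoryless) model.

    A reduced model fitted only to the observable's stationary average
    shares the overlay minimum s* but typically has a larger asymptotic
    variance, overestimating the fluctuation frequencies.
    """
    if model_full.state_space.n_neurons != model_reduced.state_space.n_neurons:
        raise ValueError("models must share the population size")
    raster = sample(model_full, SampleSpec(length=T, seed=seed))
    wavg = sliding_window_averages(raster, observable, window)
    counts, edges = np.histogram(wavg, bins=n_bins, density=True)
    lo, hi = edges[0], edges[-1]
    span = hi - lo
    s_grid = np.linspace(max(lo - 0.25 * span, 1e-6), min(hi + 0.25 * span, 1 - 1e-6), n_s)
    _, over_full = fluctuation_overlay(model_full, observable, window, s_grid)
    _, over_red = fluctuation_overlay(model_reduced, observable, window, s_grid)
    return FluctuationExperiment(
        window_averages=wavg,
        hist_counts=counts,
        hist_edges=edges,
        s_grid=s_grid,
        overlay_full=over_full,
        overlay_reduced=over_red,
        var_full=asymptotic_variance(model_full, observable),
        var_reduced=asymptotic_variance(model_reduced, observable),
    )
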