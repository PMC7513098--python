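"""Transfer operators and maximum-entropy Markov chains.

The inference pipeline runs: energy function H -> Ruelle-Perron-Frobenius
(RPF) transfer matrix L with entries e^H on overlap-consistent transitions
-> Perron triple (rho, U, V) -> stochasticization P = (1/rho) D^-1 L D with
D = diag(V) -> invariant measure pi_i = U_i V_i / <U, V>.  The topological
pressure P[H] = ln rho is the free-energy analogue: its derivatives in the
coefficients beta give the stationary feature cumulants.

Two equivalent state-space representations are provided.  The canonical
*memory* representation lumps states to (R-1)-blocks (single spike patterns
when R <= 2), matching the compact matrices usually printed for small
examples; the literal *blocks* representation keeps full R-blocks and is
retained for conformance testing.  Both share the Perron eigenvalue.

State encoding: neuron 0 is the least-significant bit of a pattern, and
within a multi-pattern word the earliest pattern occupies the lowest-order
bit group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import EnergyFunction, FeatureMonomial

__all__ = [
    "StateSpace",
    "TransferOperator",
    "MarkovModel",
    "build_transfer",
    "stochasticize",
    "build_model",
    "pressure",
    "model_expectation",
    "transition_observable_matrix",
    "ks_entropy",
    "gibbs_bound_diagnostic",
    "GibbsBoundReport",
    "detailed_balance_residual",
    "block_log_probability",
    "match_state_order",
    "save_model",
    "load_model",
]

#: hard cap on the dense state-space size, in bits (2^20 states)
MAX_STATE_BITS = 20
#: largest state count solved with the dense eigensolver
DENSE_EIG_LIMIT = 4096
#: residual tolerance for the Perron eigenpair
EIG_TOL = 1e-12


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of binary words of ``word_length`` spike patterns.

    For the memory representation of a range-R chain, ``word_length`` is
    max(R-1, 1); for the blocks representation it is R.  States are
    integers in [0, 2^(N*word_length)); ``decode`` returns the time-major
    (word_length, N) binary block.
    """

    n_neurons: int
    word_length: int

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.word_length < 1:
            raise ValueError("n_neurons and word_length must be >= 1")
        bits = self.n_neurons * self.word_length
        if bits > MAX_STATE_BITS:
            raise ValueError(
                f"state space needs {bits} bits (> {MAX_STATE_BITS}); "
                "dense transfer-matrix build refused"
            )

    @property
    def n_states(self) -> int:
        return 1 << (self.n_neurons * self.word_length)

    @property
    def n_patterns(self) -> int:
        return 1 << self.n_neurons

    def decode(self, state: int) -> np.ndarray:
        """State integer -> (word_length, n_neurons) binary block."""
        bits = np.arange(self.n_neurons * self.word_length)
        arr = (state >> bits) & 1
        return arr.reshape(self.word_length, self.n_neurons).astype(np.uint8)

    def encode(self, block: np.ndarray) -> int:
        block = np.asarray(block).reshape(self.word_length, self.n_neurons)
        bits = np.arange(self.n_neurons * self.word_length)
        return int((block.astype(np.int64).ravel() << bits).sum())

    def successor(self, state: int, pattern: int) -> int:
        """Next state after appending ``pattern`` (integer-coded) and
        dropping the oldest pattern (overlap/shift condition)."""
        N = self.n_neurons
        return (state >> N) | (pattern << (N * (self.word_length - 1)))

    def pattern_array(self, pattern: int) -> np.ndarray:
        bits = np.arange(self.n_neurons)
        return ((pattern >> bits) & 1).astype(np.uint8)


@dataclass
class TransferOperator:
    """RPF matrix with its Perron triple.

    ``matrix[i, j] = e^{H(block of i -> j)}`` on allowed transitions and 0
    otherwise; ``rho`` is the Perron eigenvalue, ``U``/``V`` the strictly
    positive left/right eigenvectors normalized so that max(V) = 1 and
    <U, V> = 1; ``pressure = ln(rho)``.
    """

    energy: EnergyFunction
    state_space: StateSpace
    matrix: np.ndarray
    rho: float
    U: np.ndarray
    V: np.ndarray
    representation: str = "memory"

    @property
    def pressure(self) -> float:
        return float(np.log(self.rho))


@dataclass
class MarkovModel:
    """The maximum-entropy Markov chain: stochastic matrix P with
    invariant measure pi, carrying its generating transfer operator."""

    energy: EnergyFunction
    transfer: TransferOperator
    P: np.ndarray
    pi: np.ndarray

    @property
    def state_space(self) -> StateSpace:
        return self.transfer.state_space

    @property
    def range(self) -> int:
        return self.energy.range

    @property
    def pressure(self) -> float:
        return self.transfer.pressure


# ---------------------------------------------------------------------------
# transfer matrix construction


def _transition_block(space: StateSpace, state: int, pattern: int, R: int) -> np.ndarray:
    """The R-block realized by appending ``pattern`` to ``state``.

    For R >= 2 (memory representation, word_length = R-1) the block is the
    state's patterns followed by the new pattern; for R = 1 it is the new
    (destination) pattern alone.
    """
    if R == 1:
        return space.pattern_array(pattern).reshape(1, -1)
    return np.vstack([space.decode(state), space.pattern_array(pattern).reshape(1, -1)])


def build_transfer(energy: EnergyFunction, representation: str = "memory") -> TransferOperator:
    """Build the RPF transfer matrix of an energy function.

    memory (default)
        States are (R-1)-blocks (single patterns for R <= 2); entry (u, v)
        is e^H of the R-block formed by u followed by v's newest pattern,
        on overlap-consistent pairs.  For R = 1 every transition is
        allowed and the entry is e^{H(v)} (destination convention).
    blocks
        States are full R-blocks; entry (y, w) is e^{H(w)} on
        overlap-consistent pairs.  Exponentially larger but literal;
        shares rho with the memory representation.
    """
    if representation not in ("memory", "blocks"):
        raise ValueError(f"unknown representation {representation!r}")
    R = energy.range
    N = energy.n_neurons
    word = R if representation == "blocks" else max(R - 1, 1)
    space = StateSpace(N, word)
    n, npat = space.n_states, space.n_patterns

    # energy of every R-block, indexed by the block's integer code
    bspace = StateSpace(N, R) if R * N <= MAX_STATE_BITS else None
    if bspace is None:  # pragma: no cover - guarded by StateSpace cap
        raise ValueError("R*N too large for dense build")
    H_vals = np.array([energy.evaluate(bspace.decode(b)) for b in range(bspace.n_states)])

    L = np.zeros((n, n))
    states = np.arange(n)
    for q in range(npat):
        succ = (states >> N) | (q << (N * (word - 1)))
        if representation == "memory":
            if R == 1:
                # destination convention: e^{H(w)} for all source states
                L[:, q] = np.exp(H_vals[q])
                continue
            rblock = states | (q << (N * (R - 1)))  # word == R-1
        else:
            rblock = succ if R > 1 else q  # destination R-block
            if R == 1:
                L[:, q] = np.exp(H_vals[q])
                continue
        L[states, succ] = np.exp(H_vals[rblock])

    rho, U, V = _perron(L)
    return TransferOperator(energy, space, L, rho, U, V, representation)


def _perron(L: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Perron eigenvalue and positive left/right eigenvectors of a
    primitive non-negative matrix."""
    n = L.shape[0]
    if n <= DENSE_EIG_LIMIT:
        w, VR = np.linalg.eig(L)
        i = int(np.argmax(w.real))
        rho = float(w[i].real)
        V = VR[:, i].real
        wl, VL = np.linalg.eig(L.T)
        j = int(np.argmax(wl.real))
        U = VL[:, j].real
        # Perron dominance: strictly larger modulus than every other mode
        others = np.delete(np.abs(w), i)
        if others.size and others.max() >= rho * (1 - 1e-12):
            sub = float(others.max())
            if sub >= rho:
                raise np.linalg.LinAlgError(
                    f"no strictly dominant eigenvalue (rho={rho}, next={sub})"
                )
    else:
        from scipy.sparse import csr_matrix
        from scipy.sparse.linalg import eigs

        Ls = csr_matrix(L)
        w, VR = eigs(Ls, k=1, which="LR")
        rho = float(w[0].real)
        V = VR[:, 0].real
        wl, VL = eigs(Ls.T, k=1, which="LR")
        U = VL[:, 0].real
    V = V if V.sum() > 0 else -V
    U = U if U.sum() > 0 else -U
    if (V <= 0).any() or (U <= 0).any():
        raise np.linalg.LinAlgError("Perron eigenvectors not strictly positive")
    scale = max(1.0, float(np.abs(L).max()))
    res = max(
        float(np.abs(L @ V - rho * V).max() / (scale * np.abs(V).max())),
        float(np.abs(U @ L - rho * U).max() / (scale * np.abs(U).max())),
    )
    if res > EIG_TOL * 100:
        raise np.linalg.LinAlgError(
            f"eigensolve did not converge: relative residual {res:.3e}"
        )
    V = V / V.max()
    U = U / (U @ V)
    return rho, U, V


def stochasticize(transfer: TransferOperator) -> MarkovModel:
    """Convert the RPF matrix into the MEMC: P = (1/rho) D^-1 L D with
    D = diag(V), and pi_i = U_i V_i / <U, V>."""
    L, V, U, rho = transfer.matrix, transfer.V, transfer.U, transfer.rho
    P = L * V[None, :] / (rho * V[:, None])
    pi = U * V
    pi = pi / pi.sum()
    rows = P.sum(axis=1)
    if np.abs(rows - 1).max() > 1e-10:
        raise np.linalg.LinAlgError(
            f"stochasticization failed: max |row sum - 1| = {np.abs(rows - 1).max():.3e}"
        )
    return MarkovModel(transfer.energy, transfer, P, pi)


def build_model(energy: EnergyFunction, representation: str = "memory") -> MarkovModel:
    """Convenience: build_transfer followed by stochasticize."""
    return stochasticize(build_transfer(energy, representation))


# ---------------------------------------------------------------------------
# stationary functionals


def pressure(model: MarkovModel) -> float:
    """Topological pressure P[H] = ln rho (nats/bin)."""
    return model.pressure


def transition_observable_matrix(model: MarkovModel, observable) -> np.ndarray:
    """Dense matrix O with O[i, j] = f(R-block of transition i -> j) on
    allowed transitions (0 elsewhere, aligned with P's support).

    ``observable`` is a FeatureMonomial (range <= R; evaluated on the
    leading patterns of the transition block) or any callable taking a
    time-major (R, N) block.
    """
    space = model.state_space
    R = model.range
    if isinstance(observable, FeatureMonomial):
        if observable.range > R:
            raise ValueError(
                f"feature range {observable.range} exceeds model range {R}"
            )
        if observable.max_neuron >= space.n_neurons:
            raise ValueError(
                f"feature references neuron {observable.max_neuron} but model has "
                f"{space.n_neurons} neurons"
            )
        func = observable.evaluate
    else:
        func = observable
    O = np.zeros_like(model.P)
    blocks_rep = model.transfer.representation == "blocks" and R >= 2
    for s in range(space.n_states):
        for q in range(space.n_patterns):
            j = space.successor(s, q)
            if blocks_rep:
                # destination state is itself the transition's R-block
                if model.P[s, j] > 0:
                    O[s, j] = func(space.decode(j))
            else:
                O[s, j] = func(_transition_block(space, s, q, R))
    return O


def model_expectation(model: MarkovModel, observable) -> float:
    """Stationary expectation E_p{f} = sum_ij pi_i P_ij f(block(i->j)).

    Equals the derivative of the pressure in the conjugate coefficient
    when f is one of the model's features.
    """
    O = transition_observable_matrix(model, observable)
    return float(model.pi @ (model.P * O) @ np.ones(model.P.shape[1]))


def ks_entropy(model: MarkovModel) -> float:
    """Kolmogorov-Sinai entropy rate -sum_i pi_i sum_j P_ij ln P_ij
    (nats/bin), with 0 ln 0 := 0.  Reduces to the Shannon entropy of pi
    for i.i.d. (range-one) chains."""
    P, pi = model.P, model.pi
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(P > 0, P * np.log(P), 0.0)
    return float(-(pi @ term.sum(axis=1)))


def detailed_balance_residual(model: MarkovModel) -> float:
    """max_ij |pi_i P_ij - pi_j P_ji|; zero iff the chain is reversible."""
    flux = model.pi[:, None] * model.P
    return float(np.abs(flux - flux.T).max())


# ---------------------------------------------------------------------------
# Gibbs-bound diagnostic


@dataclass
class GibbsBoundReport:
    """Per-length extrema of g_n = ln p{block} - (sum_k H(sub-blocks) - n P[H]).

    The Gibbs property bounds g_n uniformly in n; ``trend`` is the slope
    of the per-n midpoint against n (should be ~0) and ``passed`` holds
    when the spread shows no growth with n.
    """

    lengths: list[int]
    g_min: list[float]
    g_max: list[float]
    spread: float
    trend: float
    passed: bool


def gibbs_bound_diagnostic(model: MarkovModel, n_max: int, trend_tol: float = 1e-8) -> GibbsBoundReport:
    """Scan all spike blocks of lengths R..n_max and check the two-sided
    Gibbs bound: ln p{block} minus (sum of sub-block energies - n*P[H])
    stays in a band whose width does not grow with n."""
    R = model.range
    N = model.state_space.n_neurons
    if n_max < R:
        raise ValueError("n_max must be at least the model range")
    if n_max * N > 22:
        raise ValueError("n_max too large to enumerate all blocks")
    bspace = StateSpace(N, R) if R * N <= MAX_STATE_BITS else None
    H_vals = np.array([model.energy.evaluate(bspace.decode(b)) for b in range(bspace.n_states)])
    lnP = np.where(model.P > 0, np.log(np.where(model.P > 0, model.P, 1.0)), -np.inf)
    lnpi = np.log(model.pi)
    m = max(R - 1, 1)
    word_mask = (1 << (N * m)) - 1
    rmask = (1 << (N * R)) - 1
    P_H = model.pressure

    lengths, gmin, gmax, mids = [], [], [], []
    for n in range(R, n_max + 1):
        blocks = np.arange(1 << (N * n), dtype=np.int64)
        # state (memory word) at each step k: patterns k..k+m-1
        logp = lnpi[blocks & word_mask]
        n_steps = n - m if R >= 2 else n - 1
        for k in range(n_steps):
            s = (blocks >> (N * k)) & word_mask
            t = (blocks >> (N * (k + 1))) & word_mask
            logp = logp + lnP[s, t]
        hsum = np.zeros(len(blocks))
        for k in range(n - R + 1):
            hsum += H_vals[(blocks >> (N * k)) & rmask]
        g = logp - (hsum - n * P_H)
        lengths.append(n)
        gmin.append(float(g.min()))
        gmax.append(float(g.max()))
        mids.append(0.5 * (g.min() + g.max()))
    spread = float(max(gmax) - min(gmin))
    if len(lengths) >= 2:
        trend = float(np.polyfit(lengths, mids, 1)[0])
    else:
        trend = 0.0
    widths = [hi - lo for lo, hi in zip(gmin, gmax)]
    growth = widths[-1] - widths[0] if len(widths) >= 2 else 0.0
    passed = abs(trend) <= max(trend_tol, 1e-10) and growth <= 1e-8
    return GibbsBoundReport(lengths, gmin, gmax, spread, trend, passed)


# ---------------------------------------------------------------------------
# block probabilities (used by the irreversibility module)


def block_log_probability(model: MarkovModel, patterns: np.ndarray) -> float:
    """ln p of a concrete pattern sequence (array of integer-coded
    patterns) under the stationary chain."""
    space = model.state_space
    N = space.n_neurons
    R = model.range
    m = max(R - 1, 1)
    patterns = np.asarray(patterns, dtype=np.int64)
    if len(patterns) < m:
        raise ValueError("sequence shorter than the model memory")
    word0 = int(sum(int(p) << (N * k) for k, p in enumerate(patterns[:m])))
    logp = float(np.log(model.pi[word0]))
    s = word0
    start = m if R >= 2 else 1
    for q in patterns[start:]:
        j = space.successor(s, int(q))
        pij = model.P[s, j]
        if pij <= 0:
            raise ValueError(f"visited transition {s}->{j} has zero model probability")
        logp += float(np.log(pij))
        s = j
    return logp


# ---------------------------------------------------------------------------
# utilities


def match_state_order(P_computed: np.ndarray, P_reference: np.ndarray, n_neurons: int, atol: float = 1e-4):
    """Try both neuron-bit orders and report which permutation of the
    state labels makes ``P_computed`` match ``P_reference``.

    Printed matrices often list single-pattern states as binary strings
    whose leftmost character may be either the first or the last neuron.
    Returns (convention, permutation) or raises ValueError.
    """
    n = P_computed.shape[0]
    word = int(round(np.log2(n))) // n_neurons
    ident = np.arange(n)

    def flip_bits(state: int) -> int:
        out = 0
        for w in range(word):
            pat = (state >> (w * n_neurons)) & ((1 << n_neurons) - 1)
            rev = int(f"{pat:0{n_neurons}b}"[::-1], 2)
            out |= rev << (w * n_neurons)
        return out

    flipped = np.array([flip_bits(s) for s in ident])
    for name, perm in (("neuron0-lsb", ident), ("neuron0-msb", flipped)):
        if np.allclose(P_computed[np.ix_(perm, perm)], P_reference, atol=atol):
            return name, perm
    raise ValueError("reference matrix matches neither neuron-bit order")


def save_model(model: MarkovModel, path, include_matrices: bool = True) -> None:
    """Serialize a model to JSON: energy spec, representation, encoding
    convention, and (optionally) dense P and pi."""
    d = {
        "energy": model.energy.to_dict(),
        "representation": model.transfer.representation,
        "encoding": "neuron0-lsb, time-major",
        "pressure": model.pressure,
    }
    if include_matrices:
        d["P"] = model.P.tolist()
        d["pi"] = model.pi.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def load_model(path) -> MarkovModel:
    """Rebuild a model from its JSON serialization (recomputes the Perron
    data from the stored energy; stored matrices are cross-checked)."""
    with open(path) as fh:
        d = json.load(fh)
    energy = EnergyFunction.from_dict(d["energy"])
    model = build_model(energy, d.get("representation", "memory"))
    if "P" in d:
        stored = np.asarray(d["P"])
        if stored.shape != model.P.shape or np.abs(stored - model.P).max() > 1e-6:
            warnings.warn("stored transition matrix disagrees with rebuilt model")
    return model
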