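"""Spatiotemporal monomial features and energy functions.

A *feature* is a binary monomial over a spike block: a product of selected
spike states ``x_d^{(n)}`` indexed by a time delay ``d`` (in bins) and a
neuron index ``n`` (0-based).  Its value is 1 exactly when every indexed
state is 1.  The *range* R of a feature is ``max(delay) + 1`` — the number
of consecutive time bins it looks at.

An *energy* (or potential) is a linear combination ``H(b) = sum_k beta_k
f_k(b)`` of features with real Lagrange multipliers ``beta``.  Energies
drive the transfer-matrix construction in :mod:`memc.chain`.

Spike blocks are passed around as 2-D integer arrays of shape
``(length, n_neurons)``, time-major: ``block[d, n]`` is the spike state of
neuron ``n`` at delay ``d``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureMonomial",
    "EnergyFunction",
    "standard_feature_sets",
    "load_feature_spec",
    "dump_feature_spec",
]


def _auto_label(terms: tuple[tuple[int, int], ...]) -> str:
    return "*".join(f"x{d}_n{n}" for d, n in terms)


@dataclass(frozen=True)
class FeatureMonomial:
    """A product of spike states, each addressed by (delay, neuron).

    Parameters
    ----------
    terms
        Iterable of ``(delay, neuron)`` pairs, both 0-based non-negative
        integers.  Must be non-empty and duplicate-free.
    label
        Optional display name; auto-generated (e.g. ``"x0_n1*x1_n0"``)
        when omitted.
    """

    terms: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        terms = tuple(sorted((int(d), int(n)) for d, n in self.terms))
        if not terms:
            raise ValueError("feature must have at least one (delay, neuron) term")
        if len(set(terms)) != len(terms):
            raise ValueError(f"duplicate terms in feature: {terms}")
        for d, n in terms:
            if d < 0 or n < 0:
                raise ValueError(f"delays and neuron indices must be >= 0, got {(d, n)}")
        object.__setattr__(self, "terms", terms)
        if not self.label:
            object.__setattr__(self, "label", _auto_label(terms))

    @property
    def range(self) -> int:
        """Temporal range R = max delay + 1."""
        return max(d for d, _ in self.terms) + 1

    @property
    def max_neuron(self) -> int:
        return max(n for _, n in self.terms)

    def evaluate(self, block: np.ndarray) -> int:
        """Evaluate on a spike block of shape (length >= R, n_neurons).

        Returns 1 iff every indexed spike state is 1.  Entries of the
        block beyond the feature's range never affect the value.
        """
        block = np.asarray(block)
        if block.ndim != 2:
            raise ValueError("block must be 2-D (length, n_neurons)")
        if block.shape[0] < self.range:
            raise ValueError(
                f"block of length {block.shape[0]} shorter than feature range {self.range}"
            )
        if block.shape[1] <= self.max_neuron:
            raise ValueError(
                f"feature references neuron {self.max_neuron} but block has "
                f"{block.shape[1]} neurons"
            )
        for d, n in self.terms:
            if not block[d, n]:
                return 0
        return 1

    def __call__(self, block: np.ndarray) -> int:
        return self.evaluate(block)

    def to_dict(self) -> list[dict]:
        return [{"delay": d, "neuron": n} for d, n in self.terms]

    @classmethod
    def from_dict(cls, spec: list[dict], label: str = "") -> "FeatureMonomial":
        return cls(tuple((t["delay"], t["neuron"]) for t in spec), label=label)


@dataclass(frozen=True)
class EnergyFunction:
    """Linear combination H = sum_k beta_k f_k of monomial features.

    ``range`` is the maximum feature range; the transfer matrix built from
    this energy acts on blocks of that length.  Coefficients must be
    finite (H > -infinity keeps the transfer matrix primitive).
    """

    features: tuple[FeatureMonomial, ...]
    coefficients: tuple[float, ...]
    n_neurons: int

    def __post_init__(self) -> None:
        feats = tuple(self.features)
        coeffs = tuple(float(b) for b in self.coefficients)
        if len(feats) < 1:
            raise ValueError("energy needs at least one feature")
        if len(feats) != len(coeffs):
            raise ValueError("features and coefficients length mismatch")
        if not all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite (H > -inf)")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for f in feats:
            if f.max_neuron >= self.n_neurons:
                raise ValueError(
                    f"feature {f.label} references neuron {f.max_neuron} "
                    f"but n_neurons={self.n_neurons}"
                )
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def range(self) -> int:
        return max(f.range for f in self.features)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)

    def evaluate(self, block: np.ndarray) -> float:
        """H on a block of exactly ``self.range`` patterns."""
        block = np.asarray(block)
        if block.shape[0] != self.range:
            raise ValueError(
                f"energy of range {self.range} requires a block of that length, "
                f"got {block.shape[0]}"
            )
        return float(
            sum(b * f.evaluate(block) for b, f in zip(self.coefficients, self.features))
        )

    def __call__(self, block: np.ndarray) -> float:
        return self.evaluate(block)

    def with_coefficients(self, beta) -> "EnergyFunction":
        return EnergyFunction(self.features, tuple(np.asarray(beta, float)), self.n_neurons)

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "range": self.range,
            "features": [f.to_dict() for f in self.features],
            "labels": [f.label for f in self.features],
            "coefficients": list(self.coefficients),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyFunction":
        labels = d.get("labels") or [""] * len(d["features"])
        feats = tuple(
            FeatureMonomial.from_dict(spec, label=lab)
            for spec, lab in zip(d["features"], labels)
        )
        return cls(feats, tuple(d["coefficients"]), d["n_neurons"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "EnergyFunction":
        return cls.from_dict(json.loads(s))


def standard_feature_sets(kind: str, n_neurons: int, max_delay: int = 1) -> list[FeatureMonomial]:
    """Canonical generated feature sets, ordered lexicographically.

    kind="rates"
        N singleton features x_0^{(i)} (firing rates).
    kind="ising"
        rates plus all N(N-1)/2 synchronous pairs x_0^{(i)} x_0^{(j)}.
    kind="pairwise_lagged"
        ising plus all cross-neuron pairs x_0^{(i)} x_d^{(j)}, i != j,
        for delays d = 1..max_delay.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if kind not in ("rates", "ising", "pairwise_lagged"):
        raise ValueError(f"unknown feature set kind: {kind!r}")
    feats = [FeatureMonomial(((0, i),)) for i in range(n_neurons)]
    if kind in ("ising", "pairwise_lagged"):
        for i, j in itertools.combinations(range(n_neurons), 2):
            feats.append(FeatureMonomial(((0, i), (0, j))))
    if kind == "pairwise_lagged":
        for d in range(1, max_delay + 1):
            for i in range(n_neurons):
                for j in range(n_neurons):
                    if i != j:
                        feats.append(FeatureMonomial(((0, i), (d, j))))
    return feats


def load_feature_spec(path) -> list[FeatureMonomial]:
    """Read a YAML/JSON feature-spec file: a list of features, each a list
    of {delay, neuron} objects (neurons 0-based)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [FeatureMonomial.from_dict(entry) for entry in raw]


def dump_feature_spec(features, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([f.to_dict() for f in features], fh)
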