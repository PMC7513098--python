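"""Binary spike rasters: binarization, I/O, and empirical feature averages.

A raster holds the binned spiking activity of N neurons over T time bins
as an N x T binary matrix.  Time bins are half-open intervals
``[t*dt, (t+1)*dt)``; two or more spikes of one neuron falling in the same
bin collapse to a single 1.  Neuron indices are 0-based internally (papers
in this field typically print 1-based superscripts).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMonomial

__all__ = [
    "SpikeRaster",
    "binarize_events",
    "read_events_csv",
    "empirical_average",
    "sliding_window_averages",
    "save_raster",
    "load_raster",
]


@dataclass
class SpikeRaster:
    """N x T binary spiking matrix with a time-bin width in seconds."""

    data: np.ndarray
    bin_width: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("raster data must be 2-D (neurons x time bins)")
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("raster needs at least one neuron and one time bin")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("raster entries must be exactly 0 or 1")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        self.data = data.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def block(self, start: int, length: int) -> np.ndarray:
        """Time-major spike block of shape (length, n_neurons)."""
        return self.data[:, start : start + length].T


def binarize_events(
    events, bin_width: float, n_neurons: int, duration: float
) -> SpikeRaster:
    """Bin a list of (neuron_id, spike_time) events into a binary raster.

    Entry (k, t) is 1 iff neuron k fires at least once in
    ``[t*bin_width, (t+1)*bin_width)``.  Spike times must lie in
    ``[0, duration)``; a spike exactly at the duration boundary is
    rejected rather than wrapped.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    n_bins = int(np.ceil(duration / bin_width - 1e-12))
    data = np.zeros((n_neurons, n_bins), dtype=np.uint8)
    for neuron, t in events:
        neuron = int(neuron)
        if not 0 <= neuron < n_neurons:
            raise ValueError(
                f"neuron id {neuron} out of range [0, {n_neurons})"
            )
        if not 0 <= t < duration:
            raise ValueError(
                f"spike time {t} outside [0, {duration}) for neuron {neuron}"
            )
        data[neuron, int(t / bin_width)] = 1
    return SpikeRaster(data, bin_width=bin_width)


def read_events_csv(path) -> list[tuple[int, float]]:
    """Read an event list from CSV with header ``neuron,time`` (seconds)."""
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"neuron", "time"} <= set(reader.fieldnames):
            raise ValueError("event CSV must have a 'neuron,time' header")
        for row in reader:
            events.append((int(row["neuron"]), float(row["time"])))
    return events


def empirical_average(raster: SpikeRaster, feature: FeatureMonomial) -> float:
    """Empirical time-average of a monomial feature over the raster.

    For a feature of range R and a raster of T bins this is the mean of
    the feature over the T - R + 1 blocks starting at every bin, i.e.
    ``(1/(T-R+1)) sum_i f(x_{i..i+R-1})``; for R = 1 it reduces to the
    plain mean over bins.
    """
    R = feature.range
    T = raster.n_bins
    if T < R:
        raise ValueError(
            f"sample shorter than feature range: T={T} < R={R}"
        )
    if feature.max_neuron >= raster.n_neurons:
        raise ValueError(
            f"feature references neuron {feature.max_neuron} but raster has "
            f"{raster.n_neurons} neurons"
        )
    n_win = T - R + 1
    acc = np.ones(n_win, dtype=bool)
    for d, n in feature.terms:
        acc &= raster.data[n, d : d + n_win].astype(bool)
    return float(acc.mean())


def sliding_window_averages(
    raster: SpikeRaster,
    feature: FeatureMonomial,
    window: int,
    overlapping: bool = False,
) -> np.ndarray:
    """Per-window empirical averages of a feature.

    By default windows are contiguous and disjoint (floor(T/window) of
    them, trailing remainder dropped); with ``overlapping=True`` windows
    advance one bin at a time (T - window + 1 of them).
    """
    window = int(window)
    if window < feature.range:
        raise ValueError("window must be at least the feature range")
    if window > raster.n_bins:
        raise ValueError(
            f"window {window} longer than raster ({raster.n_bins} bins)"
        )
    if overlapping:
        starts = range(raster.n_bins - window + 1)
    else:
        starts = range(0, raster.n_bins - window + 1, window)
    out = [
        empirical_average(
            SpikeRaster(raster.data[:, s : s + window], raster.bin_width), feature
        )
        for s in starts
    ]
    return np.asarray(out)


def save_raster(raster: SpikeRaster, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.txt`` (whitespace-delimited 0/1 matrix, one neuron
    per row) and ``<prefix>.json`` (n_neurons, n_bins, bin_width, metadata)."""
    prefix = Path(prefix)
    txt, meta = prefix.with_suffix(".txt"), prefix.with_suffix(".json")
    np.savetxt(txt, raster.data, fmt="%d")
    with open(meta, "w") as fh:
        json.dump(
            {
                "n_neurons": raster.n_neurons,
                "n_bins": raster.n_bins,
                "bin_width": raster.bin_width,
                "metadata": raster.metadata,
            },
            fh,
            indent=2,
        )
    return txt, meta


def load_raster(prefix) -> SpikeRaster:
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".txt"), dtype=int, ndmin=2)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if data.shape != (meta["n_neurons"], meta["n_bins"]):
        raise ValueError(
            f"raster matrix shape {data.shape} disagrees with sidecar "
            f"({meta['n_neurons']}, {meta['n_bins']})"
        )
    return SpikeRaster(data, bin_width=meta["bin_width"], metadata=meta.get("metadata", {}))
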