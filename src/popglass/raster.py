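"""Spike tables, binarized rasters and their empirical pairwise statistics.

A recording is reduced to an ``N x B`` binary matrix: one row per neuron, one
column per timebin of fixed width (default 20 ms), with multiple spikes in a
bin truncated to a single 1.  All downstream models (pairwise maximum-entropy,
tree-emission HMM, readout circuits) consume either the raster itself or the
first- and second-order statistics computed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.020  # seconds


@dataclass
class SpikeTable:
    """Spike events as (neuron_id, spike_time) records.

    Parameters
    ----------
    events:
        DataFrame with columns ``neuron_id`` (integer labels) and
        ``spike_time_s`` (seconds, in ``[0, recording_duration]``).
    recording_duration:
        Total recording length in seconds.
    neuron_ids:
        Full set of neuron labels.  Defaults to the labels present in
        ``events``; pass explicitly to include silent neurons.
    """

    events: pd.DataFrame
    recording_duration: float
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        ev = self.events
        if not {"neuron_id", "spike_time_s"}.issubset(ev.columns):
            raise ValueError("events needs columns neuron_id, spike_time_s")
        t = ev["spike_time_s"].to_numpy(dtype=float)
        if len(t) and t.min() < 0:
            raise ValueError("negative spike time")
        if len(t) and t.max() > self.recording_duration:
            raise ValueError("spike time beyond recording_duration")
        if self.neuron_ids is None:
            self.neuron_ids = np.unique(ev["neuron_id"].to_numpy())
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.neuron_ids.size == 0:
            raise ValueError("empty neuron set")

    @classmethod
    def from_csv(cls, path: str | Path, recording_duration: float | None = None,
                 neuron_ids=None) -> "SpikeTable":
        ev = pd.read_csv(path)
        if recording_duration is None:
            recording_duration = float(ev["spike_time_s"].max())
        return cls(ev, recording_duration, neuron_ids)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False, columns=["neuron_id", "spike_time_s"])


@dataclass
class BinaryRaster:
    """``N x B`` binary spike raster with a fixed bin width in seconds."""

    values: np.ndarray  # uint8, neurons x bins
    bin_width: float = DEFAULT_BIN_WIDTH
    neuron_ids: np.ndarray | None = None
    trial_id: np.ndarray | None = None  # optional per-bin trial label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x bins)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.size != self.values.shape[0]:
                raise ValueError("neuron_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def spike_counts(self) -> np.ndarray:
        """Population spike count K(t) per bin."""
        return self.values.sum(axis=0)

    def subset(self, idx) -> "BinaryRaster":
        idx = np.asarray(idx)
        return BinaryRaster(self.values[idx], self.bin_width,
                            self.neuron_ids[idx], self.trial_id)

    # -- serialization ------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w", track_order=True) as f:
            d = f.create_dataset("raster", data=self.values, track_times=False)
            d.attrs["bin_width_s"] = self.bin_width
            d.attrs["neuron_ids"] = self.neuron_ids
            if self.trial_id is not None:
                f.create_dataset("trial_id", data=self.trial_id,
                                 track_times=False)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "BinaryRaster":
        with h5py.File(path, "r") as f:
            d = f["raster"]
            trial = f["trial_id"][...] if "trial_id" in f else None
            return cls(d[...], float(d.attrs["bin_width_s"]),
                       np.asarray(d.attrs["neuron_ids"]), trial)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.neuron_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, bin_width: float = DEFAULT_BIN_WIDTH):
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.uint8), bin_width,
                   df.index.to_numpy())


@dataclass
class PairwiseStats:
    """Rates, second moments and pairwise correlations of a raster.

    Both the covariance matrix and the Pearson correlation matrix are stored;
    correlation-scaling manipulations act on covariances with rates fixed.
    Neurons with rate exactly 0 or 1 are flagged ``degenerate`` (their Pearson
    correlation is undefined and they carry no pairwise constraint).
    """

    rates: np.ndarray              # p_i, probability of a spike per bin
    second_moments: np.ndarray     # m_ij = <r_i r_j>, symmetric, diag = p_i
    n_bins: int
    covariance: np.ndarray = field(init=False)
    pearson: np.ndarray = field(init=False)
    degenerate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.rates, dtype=float)
        m = np.asarray(self.second_moments, dtype=float)
        if m.shape != (p.size, p.size):
            raise ValueError("second_moments shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("second moments must be symmetric")
        self.rates, self.second_moments = p, m
        self.covariance = m - np.outer(p, p)
        sd = np.sqrt(p * (1.0 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.pearson = self.covariance / np.outer(sd, sd)
        self.degenerate = (p <= 0.0) | (p >= 1.0)
        if self.degenerate.any():
            logger.warning("%d neuron(s) with rate 0 or 1: Pearson undefined, "
                           "excluded from model fits by default",
                           int(self.degenerate.sum()))

    @property
    def n_neurons(self) -> int:
        return self.rates.size

    def frechet_bounds(self):
        """Elementwise (lower, upper) Frechet bounds on the second moments."""
        p = self.rates
        lo = np.maximum(0.0, p[:, None] + p[None, :] - 1.0)
        hi = np.minimum(p[:, None], p[None, :])
        return lo, hi

    def check_feasible(self, strict: bool = True, tol: float = 0.0) -> None:
        """Raise ``ValueError`` naming the first pair violating its bounds."""
        lo, hi = self.frechet_bounds()
        m = self.second_moments
        bad = (m < lo - tol) | (m > hi + tol)
        np.fill_diagonal(bad, False)
        if strict:
            iu = np.triu_indices(self.n_neurons, 1)
            on_edge = np.isclose(m[iu], lo[iu]) | np.isclose(m[iu], hi[iu])
            ok = ~(self.degenerate[iu[0]] | self.degenerate[iu[1]])
            if (on_edge & ok).any():
                k = int(np.flatnonzero(on_edge & ok)[0])
                raise ValueError(
                    f"moment m[{iu[0][k]},{iu[1][k]}] on Frechet boundary")
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"infeasible second moment m[{i},{j}]="
                             f"{m[i, j]:.6g} outside [{lo[i, j]:.6g}, "
                             f"{hi[i, j]:.6g}]")

    def active_subset(self) -> tuple["PairwiseStats", np.ndarray]:
        """Stats restricted to non-degenerate neurons, plus their indices."""
        keep = np.flatnonzero(~self.degenerate)
        return (PairwiseStats(self.rates[keep],
                              self.second_moments[np.ix_(keep, keep)],
                              self.n_bins), keep)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        pd.DataFrame(self.second_moments).to_csv(prefix.with_suffix(".m.csv"))
        pd.DataFrame(self.covariance).to_csv(prefix.with_suffix(".cov.csv"))
        summary = {"n_neurons": int(self.n_neurons), "n_bins": int(self.n_bins),
                   "rates": self.rates.tolist(),
                   "n_degenerate": int(self.degenerate.sum())}
        prefix.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def binarize(spikes: SpikeTable, bin_width: float = DEFAULT_BIN_WIDTH) -> BinaryRaster:
    """Discretize spike times into fixed bins, truncating >1 spike per bin.

    Bins are half-open ``[t*dt, (t+1)*dt)`` with 0-based indices; the number
    of bins is ``floor(duration / dt)`` and events falling past the last full
    bin are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(spikes.recording_duration / bin_width))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    ids = np.asarray(spikes.neuron_ids)
    row = {int(n): k for k, n in enumerate(ids)}
    values = np.zeros((ids.size, n_bins), dtype=np.uint8)
    t = spikes.events["spike_time_s"].to_numpy(dtype=float)
    n = spikes.events["neuron_id"].to_numpy()
    b = np.floor(t / bin_width).astype(np.int64)
    ok = b < n_bins
    for ni, bi in zip(n[ok], b[ok]):
        values[row[int(ni)], bi] = 1
    return BinaryRaster(values, bin_width, ids)


def spike_table_from_raster(raster: BinaryRaster) -> SpikeTable:
    """Inverse of :func:`binarize`: one spike at each occupied bin's center."""
    i, t = np.nonzero(raster.values)
    ev = pd.DataFrame({"neuron_id": raster.neuron_ids[i],
                       "spike_time_s": (t + 0.5) * raster.bin_width})
    return SpikeTable(ev, raster.n_bins * raster.bin_width, raster.neuron_ids)


def empirical_stats(raster: BinaryRaster) -> PairwiseStats:
    """Rates ``p_i``, second moments ``<r_i r_j>`` and correlations of a raster."""
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = raster.values.astype(np.float64)
    p = x.mean(axis=1)
    m = (x @ x.T) / raster.n_bins
    np.fill_diagonal(m, p)  # r_i^2 = r_i for binary units
    return PairwiseStats(p, m, raster.n_bins)


def pattern_census(raster: BinaryRaster) -> dict[str, int]:
    """Count occurrences of each distinct population pattern.

    Only meaningful when the pattern space is enumerable; refuses N > 25.
    Keys are bit-strings ordered as the raster's rows.
    """
    if raster.n_neurons > 25:
        raise ValueError("pattern census limited to N <= 25")
    weights = 1 << np.arange(raster.n_neurons, dtype=np.int64)
    codes = weights @ raster.values.astype(np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    out: dict[str, int] = {}
    for code, c in zip(uniq, counts):
        bits = "".join(str((int(code) >> k) & 1)
                       for k in range(raster.n_neurons))
        out[bits] = int(c)
    return out
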