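"""Winner-take-all readout with Hebbian and homeostatic plasticity.

A layer of readout units receives the binary population pattern through
non-negative feedforward weights.  Global inhibition lets at most one unit —
the one with the largest supra-threshold drive — win each bin.  The winner's
synapses from spiking inputs are potentiated and those from silent inputs
decay, while every unit's threshold drifts homeostatically toward a target
winning rate.  With modest redundancy (about two readouts per latent
cluster) the layer discovers the clusters without supervision.

The *ideal* readout implements the active-set rule directly: fire iff at
least K_min active-set inputs spike and no silent-set input spikes (the
silent set acts as a disynaptic veto).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .raster import BinaryRaster
from .ridges import Ridgeline

DEFAULT_PLASTICITY = dict(
    eta_plus=0.05,     # Hebbian potentiation per winning bin
    eta_minus=0.05,    # multiplicative decay of the winner's silent synapses
    eta_theta=0.01,    # homeostatic threshold step
    target_rate=None,  # winning-rate target; None -> active_bins/B/n_readouts
    w_max=1.0,
    w_init=0.2,        # scale of the random initial weights
    theta_init=0.5,
)


@dataclass
class WTACircuit:
    """Feedforward weights, thresholds and optional veto (inhibitory) weights."""

    W: np.ndarray                      # (n_readouts, N), clipped to [0, w_max]
    theta: np.ndarray                  # per-readout adaptive threshold
    V: np.ndarray | None = None        # optional veto weights (inhibitory)
    config: dict = field(default_factory=lambda: dict(DEFAULT_PLASTICITY))

    @property
    def n_readouts(self) -> int:
        return self.W.shape[0]

    def drives(self, x: np.ndarray) -> np.ndarray:
        d = self.W @ x
        if self.V is not None:
            d = d - self.V @ x
        return d

    def winner(self, x: np.ndarray) -> int:
        """Index of the winning readout for pattern x, or -1 for no winner.

        A unit wins only with positive excitatory drive exceeding its
        threshold; ties break to the lowest index (argmax convention).
        """
        d = self.drives(x)
        eligible = (d > self.theta) & (d > 0)
        if not eligible.any():
            return -1
        d = np.where(eligible, d, -np.inf)
        return int(np.argmax(d))

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W, track_times=False)
            f.create_dataset("theta", data=self.theta, track_times=False)
            if self.V is not None:
                f.create_dataset("V", data=self.V, track_times=False)
            for k, v in self.config.items():
                if v is not None:
                    f.attrs[k] = v


class IdealReadout:
    """Static unit: fire iff >= K_min active-set spikes and no silent spikes."""

    def __init__(self, active_set, silent_set, k_min: int,
                 k_max: int | None = None, n_neurons: int | None = None):
        self.active_set = np.asarray(active_set, dtype=int)
        self.silent_set = np.asarray(silent_set, dtype=int)
        self.k_min = int(k_min)
        self.k_max = None if k_max is None else int(k_max)
        self.n_neurons = n_neurons

    @classmethod
    def from_ridgeline(cls, ridge: Ridgeline,
                       enforce_k_max: bool = False) -> "IdealReadout":
        return cls(ridge.active_set, ridge.silent_set, ridge.K_min,
                   ridge.K_max if enforce_k_max else None, ridge.n_neurons)

    def fires(self, pattern: np.ndarray) -> bool:
        r = np.asarray(pattern).astype(bool)
        if r[self.silent_set].any():
            return False  # disynaptic veto from the silent set
        k = int(r[self.active_set].sum())
        if self.k_max is not None and k > self.k_max:
            return False
        return k >= self.k_min


def ideal_readout(source) -> IdealReadout:
    """Build the ideal K_min / silent-set-veto unit from a ridgeline."""
    if isinstance(source, Ridgeline):
        return IdealReadout.from_ridgeline(source)
    return IdealReadout(**source)


def ideal_circuit(ridgelines: list[Ridgeline]) -> WTACircuit:
    """Frozen circuit implementing one ideal readout per ridgeline.

    Unit excitation 1 on the active set, strong veto weights on the silent
    set, threshold K_min - 1/2; the winner is the cluster with the most
    active-set evidence.
    """
    n = ridgelines[0].n_neurons
    m = len(ridgelines)
    W = np.zeros((m, n))
    V = np.zeros((m, n))
    theta = np.empty(m)
    for k, r in enumerate(ridgelines):
        W[k, r.active_set] = 1.0
        V[k, r.silent_set] = float(n)  # any silent-set spike vetoes the unit
        theta[k] = r.K_min - 0.5
    return WTACircuit(W, theta, V)


def train(raster: BinaryRaster, n_readouts: int,
          plasticity_config: dict | None = None, seed: int = 0,
          circuit: WTACircuit | None = None, freeze: bool = False):
    """Train (or run) the WTA layer on a raster, bin by bin.

    Per bin: compute drives, pick the winner (largest supra-threshold
    positive drive; silent bins have none), apply Hebbian updates to the
    winner only — ``dW = eta_plus * r_i`` on spiking inputs, ``dW = -eta_minus
    * W`` on silent inputs — clip to ``[0, w_max]``, and move every unit's
    threshold by ``eta_theta * (won - target_rate)``.  Returns
    ``(circuit, trajectory)`` with the per-bin mean |dW| and winner sequence.
    """
    cfg = dict(DEFAULT_PLASTICITY)
    if plasticity_config:
        cfg.update(plasticity_config)
    if n_readouts < 1:
        raise ValueError("need at least one readout")
    x = raster.values.astype(np.float64)
    n, B = x.shape
    if cfg["target_rate"] is None:
        active = float((x.sum(axis=0) > 0).mean())
        cfg["target_rate"] = active / n_readouts
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if circuit is None:
        W = rng.uniform(0, cfg["w_init"], size=(n_readouts, n))
        theta = np.full(n_readouts, cfg["theta_init"])
        circuit = WTACircuit(W, theta, None, cfg)
    else:
        circuit = WTACircuit(circuit.W.copy(), circuit.theta.copy(),
                             None if circuit.V is None else circuit.V.copy(),
                             cfg)
    W, theta = circuit.W, circuit.theta
    dw_trace = np.zeros(B)
    winners = np.full(B, -1, dtype=np.int64)
    won = np.zeros(n_readouts)
    for t in range(B):
        xt = x[:, t]
        k = circuit.winner(xt)
        winners[t] = k
        if freeze:
            continue
        won[:] = 0.0
        if k >= 0:
            won[k] = 1.0
            old = W[k].copy()
            spk = xt > 0
            W[k, spk] += cfg["eta_plus"] * xt[spk]
            W[k, ~spk] -= cfg["eta_minus"] * W[k, ~spk]
            np.clip(W[k], 0.0, cfg["w_max"], out=W[k])
            dw_trace[t] = np.abs(W[k] - old).mean()
        theta += cfg["eta_theta"] * (won - cfg["target_rate"])
    trajectory = {"mean_abs_dw": dw_trace, "winners": winners,
                  "final_rates": np.array([(winners == k).mean()
                                           for k in range(n_readouts)])}
    return circuit, trajectory


@dataclass
class ReadoutReport:
    """Tuning, confusion and coverage of a trained readout layer."""

    tuning: np.ndarray          # (n_readouts, n_clusters) win probability
    confusion: np.ndarray       # (n_clusters, n_clusters) row-normalized
    coverage: float             # fraction of clusters with a dedicated readout
    accuracy: float             # label recovery through best-readout mapping
    readout_to_cluster: np.ndarray
    cluster_ids: np.ndarray


def evaluate(circuit: WTACircuit, raster: BinaryRaster,
             labels: np.ndarray) -> ReadoutReport:
    """Run the frozen circuit and score it against cluster labels.

    Tuning is the per-(readout, cluster) winning probability.  Each readout
    is mapped to its tuning-peak cluster; a cluster is covered when some
    readout peaks on it, and bins are scored correct when the winning
    readout maps to the bin's true cluster.
    """
    labels = np.asarray(labels)
    _, traj = train(raster, circuit.n_readouts, circuit.config,
                    circuit=circuit, freeze=True)
    winners = traj["winners"]
    clusters = np.unique(labels)
    m = circuit.n_readouts
    tuning = np.zeros((m, clusters.size))
    for j, c in enumerate(clusters):
        sel = labels == c
        if sel.any():
            for k in range(m):
                tuning[k, j] = float((winners[sel] == k).mean())
    # map each readout to the cluster it wins most often on
    r2c = np.full(m, -1, dtype=np.int64)
    for k in range(m):
        if tuning[k].max() > 0:
            r2c[k] = clusters[int(np.argmax(tuning[k]))]
    covered = np.isin(clusters, r2c[r2c >= 0])
    pred = np.where(winners >= 0, r2c[np.clip(winners, 0, None)], -1)
    accuracy = float((pred == labels).mean())
    conf = np.zeros((clusters.size, clusters.size))
    for j, c in enumerate(clusters):
        sel = labels == c
        for j2, c2 in enumerate(clusters):
            conf[j, j2] = float((pred[sel] == c2).mean())
    return ReadoutReport(tuning, conf, float(covered.mean()), accuracy,
                         r2c, clusters)


def learning_curve(mean_abs_dw: np.ndarray, block_size: int) -> np.ndarray:
    """Mean absolute weight change per contiguous time block."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    dw = np.asarray(mean_abs_dw, dtype=float)
    nb = int(np.ceil(dw.size / block_size))
    return np.array([dw[k * block_size:(k + 1) * block_size].mean()
                     for k in range(nb)])
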