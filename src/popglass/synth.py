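"""Synthetic rasters with known ground truth.

Every downstream stage is exercised on data whose generative process is known
exactly: Gibbs samples from a planted frustrated pairwise model, rasters
emitted by a Markov chain over latent modes, rate-matched independent
controls, repeat-trial ensembles sharing one latent sequence, and a random
checkerboard stimulus driving mode activations through planted spatial
filters.  All generators are pure functions of (parameters, seed); randomness
is split with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import _gibbs
from .maxent import MaxEntModel
from .raster import BinaryRaster

DEFAULT_SWEEPS_PER_SAMPLE = 10
DEFAULT_BURN_IN = 1000


def _kernel_seed(ss: np.random.SeedSequence) -> np.int64:
    return np.int64(int(ss.generate_state(1)[0]) & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# planted pairwise (Ising) models
# ---------------------------------------------------------------------------

def make_frustrated_model(n_neurons: int, J_std: float = 0.35,
                          h_level: float = -3.0, seed: int = 0) -> MaxEntModel:
    """Random zero-mean Gaussian couplings with sparse-firing fields.

    Mixed-sign couplings make the model frustrated for N >= 3 with
    probability 1.  ``h_level`` sets the baseline field; -3 gives ~5% of bins
    occupied per neuron in the absence of interactions, a typical sparse rate
    for 20 ms bins.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a = rng.normal(0.0, J_std, size=(n_neurons, n_neurons))
    J = np.triu(a, 1)
    J = J + J.T
    h = np.full(n_neurons, float(h_level)) + rng.normal(0, 0.2, n_neurons)
    return MaxEntModel(h, J)


def sample_ising(model: MaxEntModel, n_bins: int,
                 sweeps_per_sample: int = DEFAULT_SWEEPS_PER_SAMPLE,
                 burn_in: int = DEFAULT_BURN_IN, seed: int = 0,
                 bin_width: float = 0.020) -> BinaryRaster:
    """Gibbs samples from ``P(R) \\propto exp(-E(R)/T)`` as a raster.

    Single-site heat-bath updates in fixed sweep order; one retained sample
    every ``sweeps_per_sample`` sweeps after ``burn_in`` sweeps.
    """
    if not np.allclose(model.J, model.J.T):
        raise ValueError("J must be symmetric")
    ss = np.random.SeedSequence(seed)
    samples = _gibbs.gibbs_sample(model.h, model.J, float(model.T),
                                  np.int64(n_bins), np.int64(burn_in),
                                  np.int64(sweeps_per_sample),
                                  _kernel_seed(ss))
    return BinaryRaster(samples.T, bin_width)


def rate_matched_shuffle(raster: BinaryRaster, seed: int = 0) -> BinaryRaster:
    """Independently time-permute each neuron's row.

    Exactly preserves every neuron's spike count (hence rate) while
    destroying cross-neuron covariances in expectation — the matched
    independent control.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = np.empty_like(raster.values)
    for i in range(raster.n_neurons):
        values[i] = raster.values[i, rng.permutation(raster.n_bins)]
    return BinaryRaster(values, raster.bin_width, raster.neuron_ids,
                        raster.trial_id)


# ---------------------------------------------------------------------------
# planted latent modes with Markov dynamics
# ---------------------------------------------------------------------------

@dataclass
class ModeGroundTruth:
    """Known latent-mode structure: weights, emissions, Markov transitions."""

    emission_probs: np.ndarray          # (M, N) per-neuron Bernoulli prob
    transitions: np.ndarray             # (M, M) row-stochastic
    weights: np.ndarray | None = None   # stationary mode weights
    active_sets: list | None = None     # per-mode neuron index arrays
    chain_tree: bool = False            # chain-structured emissions if True
    chain_corr: float = 0.0             # P(r_child=1 | r_parent=1) boost

    def __post_init__(self) -> None:
        self.emission_probs = np.asarray(self.emission_probs, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        m = self.emission_probs.shape[0]
        if self.transitions.shape != (m, m):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if self.weights is None:
            # stationary distribution of the chain
            w, v = np.linalg.eig(self.transitions.T)
            k = int(np.argmin(np.abs(w - 1.0)))
            pi = np.real(v[:, k])
            self.weights = pi / pi.sum()
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def n_modes(self) -> int:
        return self.emission_probs.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.emission_probs.shape[1]

    def to_json(self, path: str | Path) -> None:
        d = {"emission_probs": self.emission_probs.tolist(),
             "transitions": self.transitions.tolist(),
             "weights": self.weights.tolist(),
             "active_sets": [np.asarray(a).tolist()
                             for a in (self.active_sets or [])],
             "chain_tree": self.chain_tree, "chain_corr": self.chain_corr}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModeGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["emission_probs"]), np.array(d["transitions"]),
                   np.array(d["weights"]),
                   [np.array(a) for a in d["active_sets"]] or None,
                   d["chain_tree"], d["chain_corr"])


def make_planted_modes(n_neurons: int = 40, n_modes: int = 5,
                       active_size: int = 8, p_in: float = 0.5,
                       p_out: float = 0.01, self_transition: float = 0.75,
                       chain_tree: bool = False, chain_corr: float = 0.3,
                       seed: int = 0) -> ModeGroundTruth:
    """Disjoint-active-set latent modes with a sticky Markov chain.

    Defaults are the well-separated study conditions: M=5 modes over N=40
    neurons, 8-neuron active sets spiking at 0.5 per bin inside the set and
    0.01 outside, and a self-transition of 0.75 (mean dwell time 4 bins,
    matching the few-bin cluster persistence seen in retinal recordings).
    """
    if n_modes * active_size > n_neurons:
        raise ValueError("active sets must fit disjointly")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(n_neurons)
    active = [np.sort(order[k * active_size:(k + 1) * active_size])
              for k in range(n_modes)]
    probs = np.full((n_modes, n_neurons), p_out)
    for k, a in enumerate(active):
        probs[k, a] = p_in
    off = (1.0 - self_transition) / max(n_modes - 1, 1)
    trans = np.full((n_modes, n_modes), off)
    np.fill_diagonal(trans, self_transition if n_modes > 1 else 1.0)
    return ModeGroundTruth(probs, trans, active_sets=active,
                           chain_tree=chain_tree, chain_corr=chain_corr)


def _sample_labels(truth: ModeGroundTruth, n_bins: int,
                   rng: np.random.Generator) -> np.ndarray:
    labels = np.empty(n_bins, dtype=np.int64)
    labels[0] = rng.choice(truth.n_modes, p=truth.weights)
    for t in range(1, n_bins):
        labels[t] = rng.choice(truth.n_modes, p=truth.transitions[labels[t - 1]])
    return labels


def _emit(truth: ModeGroundTruth, labels: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    n_bins = labels.size
    n = truth.n_neurons
    u = rng.random((n_bins, n))
    x = (u < truth.emission_probs[labels]).astype(np.uint8)
    if truth.chain_tree and truth.active_sets is not None:
        # chain-structured emissions inside each active set: a spiking parent
        # raises its child's probability by chain_corr (testable tree signal)
        for k, a in enumerate(truth.active_sets):
            rows = np.flatnonzero(labels == k)
            for parent, child in zip(a[:-1], a[1:]):
                base = truth.emission_probs[k, child]
                boosted = min(base + truth.chain_corr, 0.99)
                x[rows, child] = (u[rows, child]
                                  < np.where(x[rows, parent] == 1, boosted,
                                             base)).astype(np.uint8)
    return x


def sample_mode_raster(truth: ModeGroundTruth, n_bins: int, seed: int = 0,
                       bin_width: float = 0.020):
    """Sample a (raster, labels) pair from the latent-mode ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = _sample_labels(truth, n_bins, rng)
    x = _emit(truth, labels, rng)
    return BinaryRaster(x.T, bin_width), labels


def make_repeat_ensemble(truth: ModeGroundTruth, n_repeats: int,
                         n_bins: int, seed: int = 0, bin_width: float = 0.020):
    """Repeat trials: one shared latent label sequence, fresh emission noise.

    Returns ``(rasters, labels)`` where every raster was emitted from the
    same ``labels`` — the synthetic analogue of repeated stimulus
    presentations, used for reliability and error-correction analyses.
    """
    ss = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = _sample_labels(truth, n_bins, label_rng)
    rasters = []
    for rep_ss in ss.spawn(n_repeats + 1)[1:]:
        rng = np.random.default_rng(rep_ss)
        rasters.append(BinaryRaster(_emit(truth, labels, rng).T, bin_width))
    return rasters, labels


# ---------------------------------------------------------------------------
# checkerboard stimulus with planted receptive fields
# ---------------------------------------------------------------------------

@dataclass
class StimulusMovie:
    """Random flicker frames in {-1,+1}, one frame per raster bin."""

    frames: np.ndarray          # (n_pixels, n_bins)
    shape: tuple = field(default=None)  # (rows, cols) of the pixel grid

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int8)
        if self.shape is None:
            self.shape = (self.frames.shape[0], 1)

    @property
    def n_bins(self) -> int:
        return self.frames.shape[1]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=self.frames, track_times=False)
            d.attrs["shape"] = self.shape


def make_checkerboard_with_rf(truth: ModeGroundTruth, pixel_grid: tuple,
                              rf_maps: np.ndarray, n_bins: int, seed: int = 0,
                              gain: float = 1.0, bin_width: float = 0.020):
    """Checkerboard stimulus driving mode activations via planted filters.

    Frames are i.i.d. +-1 pixels.  Each bin's mode is drawn with
    ``P(mode=k | frame) \\propto w_k * exp(gain * <rf_k, frame>)`` — a
    monotone function of the stimulus projection onto mode k's filter — and
    the population pattern is emitted from that mode.  Flat (all-zero)
    filters decouple modes from the stimulus.
    """
    rows, cols = pixel_grid
    n_pix = rows * cols
    rf = np.asarray(rf_maps, dtype=float)
    if rf.shape != (truth.n_modes, n_pix):
        raise ValueError("rf_maps must be (n_modes, n_pixels)")
    ss = np.random.SeedSequence(seed)
    s_stim, s_lab, s_emit = ss.spawn(3)
    rng_s = np.random.default_rng(s_stim)
    frames = rng_s.choice(np.array([-1, 1], dtype=np.int8),
                          size=(n_pix, n_bins))
    z = rf @ frames  # (M, n_bins) stimulus projections
    logits = np.log(truth.weights)[:, None] + gain * z
    logits -= logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    rng_l = np.random.default_rng(s_lab)
    u = rng_l.random(n_bins)
    labels = (u[None, :] > np.cumsum(p, axis=0)).sum(axis=0)
    rng_e = np.random.default_rng(s_emit)
    x = _emit(truth, labels, rng_e)
    return (StimulusMovie(frames, (rows, cols)),
            BinaryRaster(x.T, bin_width), labels)
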