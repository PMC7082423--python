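"""Geometry of the fitted probability landscape: local maxima and ridges.

A *soft local maximum* at spike count K is a pattern whose model probability
cannot be increased by swapping any single spiking neuron for a silent one
(K held fixed).  Chaining soft maxima across consecutive K — adding one
spiking neuron per step — traces a *ridgeline*, whose union of spiking
neurons is the cluster's active set; all other neurons form the silent set.
Membership in the cluster is then the simple rule: all spikes inside the
active set, spike count between K_min and K_max, silent set fully silent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .maxent import EXACT_N_MAX, MaxEntModel

logger = logging.getLogger(__name__)

# strict-improvement threshold: energy ties (degenerate landscapes) must not
# be mistaken for descent by floating-point rounding
STRICT_EPS = 1e-10


def _local_fields(model: MaxEntModel, r: np.ndarray) -> np.ndarray:
    return model.h + model.J @ r


def _flip_delta_e(model: MaxEntModel, r: np.ndarray, i: int) -> float:
    """Energy change from flipping neuron i."""
    f = model.h[i] + model.J[i] @ r
    return f if r[i] else -f


def _swap_delta_e(model: MaxEntModel, r: np.ndarray, a: int, b: int) -> float:
    """Energy change from deactivating ``a`` and activating ``b``."""
    fa = model.h[a] + model.J[a] @ r
    fb = model.h[b] + model.J[b] @ r
    return fa - fb + model.J[a, b]


def ascend_full(model: MaxEntModel, start: np.ndarray, seed: int = 0,
                return_trajectory: bool = False):
    """Single-flip ascent to a 1-flip local maximum of P(R).

    Randomly ordered flip proposals, accepting only strict probability
    increases; terminates (guaranteed on a finite space) when a full pass
    accepts nothing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    r = np.asarray(start, dtype=np.float64).copy()
    n = r.size
    traj = [-model.energy(r)]
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            if _flip_delta_e(model, r, i) < -STRICT_EPS:
                r[i] = 1.0 - r[i]
                improved = True
                traj.append(-model.energy(r))
    pattern = r.astype(np.uint8)
    return (pattern, np.array(traj)) if return_trajectory else pattern


def is_flip_local_max(model: MaxEntModel, pattern: np.ndarray) -> bool:
    r = np.asarray(pattern, dtype=np.float64)
    return all(_flip_delta_e(model, r, i) >= -STRICT_EPS
               for i in range(r.size))


def is_swap_local_max(model: MaxEntModel, pattern: np.ndarray) -> bool:
    r = np.asarray(pattern, dtype=np.float64)
    act = np.flatnonzero(r == 1)
    sil = np.flatnonzero(r == 0)
    return all(_swap_delta_e(model, r, a, b) >= -STRICT_EPS
               for a in act for b in sil)


@dataclass
class SoftLocalMax:
    """Fixed-K local maximum with a robustness count over search paths."""

    pattern: np.ndarray
    K: int
    energy: float
    log_prob: float | None
    robustness: int      # number of independent search paths agreeing
    n_paths: int

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(self.pattern == 1)

    @property
    def robust(self) -> bool:
        return self.robustness == self.n_paths


def _swap_ascend_once(model: MaxEntModel, start: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    r = start.astype(np.float64).copy()
    improved = True
    while improved:
        improved = False
        act = np.flatnonzero(r == 1)
        sil = np.flatnonzero(r == 0)
        pairs = [(a, b) for a in act for b in sil]
        for k in rng.permutation(len(pairs)):
            a, b = pairs[k]
            if r[a] == 1 and r[b] == 0 \
                    and _swap_delta_e(model, r, a, b) < -STRICT_EPS:
                r[a], r[b] = 0.0, 1.0
                improved = True
                break  # re-enumerate swaps from the new pattern
    return r.astype(np.uint8)


def _soft_max_from(model: MaxEntModel, pattern: np.ndarray,
                   energy: float) -> "SoftLocalMax":
    lp = None
    if model.n_neurons <= EXACT_N_MAX:
        lp = float(model.log_probability(pattern))
    return SoftLocalMax(pattern, int(pattern.sum()), energy, lp, 0, 0)


def ascend_fixed_K(model: MaxEntModel, start: np.ndarray, n_paths: int = 10,
                   seed: int = 0) -> SoftLocalMax:
    """Stochastic swap-ascent at fixed spike count K.

    Repeats the ascent over ``n_paths`` independent proposal orderings from
    the same start; the endpoint is *robust* when all paths agree, otherwise
    the modal endpoint is returned with its agreement count.
    """
    start = np.asarray(start, dtype=np.uint8)
    if start.sum() < 1:
        raise ValueError("fixed-K ascent needs at least one spike")
    ss = np.random.SeedSequence(seed)
    endpoints = []
    for child in ss.spawn(n_paths):
        rng = np.random.default_rng(child)
        endpoints.append(tuple(_swap_ascend_once(model, start, rng)))
    uniq, counts = np.unique(np.array(endpoints, dtype=np.uint8),
                             axis=0, return_counts=True)
    # modal endpoint; ties broken by lower energy then lexicographic order
    energies = np.asarray(model.energy(uniq.astype(float)))
    order = np.lexsort((energies, -counts))
    best = order[0]
    sm = _soft_max_from(model, uniq[best], float(energies[best]))
    sm.robustness = int(counts[best])
    sm.n_paths = n_paths
    return sm


@dataclass
class Ridgeline:
    """Chain of soft local maxima at K = K_min..K_max with its neuron sets."""

    chain: list                      # SoftLocalMax, ordered by K
    n_neurons: int
    split_at: list = field(default_factory=list)   # K values where it split
    terminated: str = "k_limit"
    matched_mode: int | None = None

    @property
    def K_min(self) -> int:
        return self.chain[0].K

    @property
    def K_max(self) -> int:
        return self.chain[-1].K

    @property
    def active_set(self) -> np.ndarray:
        mask = np.zeros(self.n_neurons, dtype=bool)
        for sm in self.chain:
            mask[sm.pattern == 1] = True
        return np.flatnonzero(mask)

    @property
    def silent_set(self) -> np.ndarray:
        mask = np.ones(self.n_neurons, dtype=bool)
        mask[self.active_set] = False
        return np.flatnonzero(mask)

    def to_dict(self) -> dict:
        return {"chain": [sm.active.tolist() for sm in self.chain],
                "K_min": self.K_min, "K_max": self.K_max,
                "active_set": self.active_set.tolist(),
                "silent_set": self.silent_set.tolist(),
                "split_at": self.split_at, "terminated": self.terminated,
                "matched_mode": self.matched_mode}


def save_ridgelines(ridgelines: list, path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in ridgelines],
                                     indent=1))


def trace_ridgeline(model: MaxEntModel, softmax: SoftLocalMax,
                    K_limit: int | None = None, seed: int = 0,
                    n_paths: int = 10, log_prob_window: float = np.log(10.0),
                    max_branches: int = 8) -> list[Ridgeline]:
    """Trace ridgelines upward in K from a soft local maximum.

    At each step every silent neuron is tentatively switched on and a
    fixed-K ascent is run from the augmented pattern.  Endpoints that are
    one-spike supersets of the current pattern extend the chain; two or more
    distinct robust superset endpoints within ``log_prob_window`` of the best
    constitute a split, and every branch is traced.  The trace terminates at
    ``K_limit`` or when no ascent stays in the chain's neighborhood.
    Returns one :class:`Ridgeline` per traced branch.
    """
    n = model.n_neurons
    if K_limit is None:
        K_limit = n
    ss = np.random.SeedSequence(seed)
    results: list[Ridgeline] = []
    stack = [([softmax], [])]  # (chain so far, split annotations)
    while stack and len(results) < max_branches:
        chain, splits = stack.pop()
        while True:
            cur = chain[-1]
            if cur.K >= K_limit:
                results.append(Ridgeline(chain, n, splits, "k_limit"))
                break
            silent = np.flatnonzero(cur.pattern == 0)
            endpoints: dict[tuple, SoftLocalMax] = {}
            for j in silent:
                aug = cur.pattern.copy()
                aug[j] = 1
                child = ss.spawn(1)[0]
                sm = ascend_fixed_K(model, aug, n_paths,
                                    int(child.generate_state(1)[0]
                                        & 0x7FFFFFFF))
                # chain locality: endpoint must contain the current pattern
                if (sm.pattern >= cur.pattern).all():
                    key = tuple(sm.pattern)
                    if key not in endpoints or not endpoints[key].robust:
                        endpoints[key] = sm
            if not endpoints:
                results.append(Ridgeline(chain, n, splits, "left_neighborhood"))
                break
            cands = sorted(endpoints.values(), key=lambda s: s.energy)
            best_e = cands[0].energy
            branches = [s for s in cands
                        if s.robust and (s.energy - best_e) / model.T
                        <= log_prob_window]
            if not branches:
                branches = [cands[0]]
            if len(branches) > 1:
                splits = splits + [cur.K + 1]
                for extra in branches[1:]:
                    stack.append((chain + [extra], splits))
            chain = chain + [branches[0]]
    return results


def membership_rule(ridgeline: Ridgeline):
    """Predicate: pattern belongs to the ridge's cluster.

    True iff every spike lies in the active set (silent-set veto) and the
    spike count satisfies K_min <= K <= K_max.
    """
    active = np.zeros(ridgeline.n_neurons, dtype=bool)
    active[ridgeline.active_set] = True
    kmin, kmax = ridgeline.K_min, ridgeline.K_max

    def member(pattern: np.ndarray) -> bool:
        r = np.asarray(pattern).astype(bool)
        if r[~active].any():
            return False
        k = int(r.sum())
        return kmin <= k <= kmax

    return member


def match_ridges_to_hmm(ridgelines: list, hmm_model) -> list[dict]:
    """Assign each ridge's chain members to HMM modes; majority label + purity."""
    from .raster import BinaryRaster
    from .treehmm import assign

    out = []
    for ridge in ridgelines:
        pats = np.array([sm.pattern for sm in ridge.chain], dtype=np.uint8)
        labels = assign(hmm_model, BinaryRaster(pats.T)).labels
        vals, counts = np.unique(labels, return_counts=True)
        k = int(np.argmax(counts))
        ridge.matched_mode = int(vals[k])
        out.append({"matched_mode": int(vals[k]),
                    "purity": float(counts[k] / labels.size),
                    "n_members": int(labels.size)})
    return out
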