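"""Hidden Markov model with tree-structured emissions over binary patterns.

The latent-variable model of population activity is a mixture over M modes,

    P(R) = sum_alpha w_alpha Q_alpha(R),
    Q_alpha(R) = P_alpha(r_root) * prod_{<i,j> edges} P_alpha(r_i | r_j),

where each mode's emission distribution factorizes over an acyclic spanning
graph (a Chow-Liu tree), and the mode sequence follows a first-order Markov
chain P(alpha_{t+1} | alpha_t).  Fitting is EM: forward-backward over the
mode chain, then per-mode maximum-weight spanning trees on posterior-weighted
pairwise mutual information.  A pattern R* is mapped to its cluster by
``alpha* = argmax_alpha w_alpha Q_alpha(R*)`` (static MAP), or by a greedy
one-step filter conditioning on the previous label when temporal dynamics
are requested.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .raster import BinaryRaster
from .synth import StimulusMovie

logger = logging.getLogger(__name__)

LAPLACE = 0.5  # pseudo-count on all conditional tables


# ---------------------------------------------------------------------------
# tree-structured emission distributions
# ---------------------------------------------------------------------------

@dataclass
class TreeMode:
    """One mode's emission: a rooted forest with 2x2 conditional tables.

    ``parent[i] = -1`` marks a root (its table rows both hold the marginal);
    an all-root forest is an independent (edgeless) emission.
    ``log_table[i, s, v] = log P(r_i = v | r_parent(i) = s)``.
    """

    parent: np.ndarray
    log_table: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.log_table = np.asarray(self.log_table, dtype=float)
        n = self.parent.size
        if self.log_table.shape != (n, 2, 2):
            raise ValueError("log_table must be (N, 2, 2)")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        n = self.parent.size
        seen = np.zeros(n, dtype=bool)
        for i in range(n):
            path = []
            j = i
            while j >= 0 and not seen[j]:
                path.append(j)
                seen[j] = True
                j = int(self.parent[j])
                if j in path:
                    raise ValueError("emission graph has a cycle")

    @property
    def n_neurons(self) -> int:
        return self.parent.size

    @classmethod
    def independent(cls, probs: np.ndarray) -> "TreeMode":
        """Edgeless emission with per-neuron Bernoulli marginals."""
        p = np.clip(np.asarray(probs, float), 1e-12, 1 - 1e-12)
        n = p.size
        tab = np.empty((n, 2, 2))
        tab[:, 0, 1] = tab[:, 1, 1] = np.log(p)
        tab[:, 0, 0] = tab[:, 1, 0] = np.log1p(-p)
        return cls(np.full(n, -1), tab)

    def log_prob(self, patterns: np.ndarray) -> np.ndarray:
        """log Q(R) for one pattern or a (B, N) batch."""
        x = np.atleast_2d(np.asarray(patterns)).astype(np.int64)
        par = np.where(self.parent < 0, np.arange(self.n_neurons), self.parent)
        xp = x[:, par]
        cols = np.arange(self.n_neurons)
        lp = self.log_table[cols[None, :], xp, x].sum(axis=1)
        return lp if np.asarray(patterns).ndim == 2 else float(lp[0])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestral sampling in topological order."""
        order = _topo_order(self.parent)
        x = np.zeros((n, self.n_neurons), dtype=np.uint8)
        p = np.exp(self.log_table[..., 1])  # P(r_i=1 | parent state)
        for i in order:
            s = x[:, self.parent[i]] if self.parent[i] >= 0 else \
                np.zeros(n, dtype=np.uint8)
            x[:, i] = (rng.random(n) < p[i, s]).astype(np.uint8)
        return x


def _topo_order(parent: np.ndarray) -> list[int]:
    n = parent.size
    children: list[list[int]] = [[] for _ in range(n)]
    roots = []
    for i, p in enumerate(parent):
        if p < 0:
            roots.append(i)
        else:
            children[p].append(i)
    order, stack = [], list(roots)
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    if len(order) != n:
        raise ValueError("parent array is not a forest")
    return order


def emission_log_prob(mode: TreeMode, pattern: np.ndarray):
    """log Q_alpha(R): root marginal plus edge conditionals."""
    return mode.log_prob(pattern)


def chow_liu(x: np.ndarray, weights: np.ndarray,
             laplace: float = LAPLACE) -> TreeMode:
    """Maximum-likelihood tree emission from weighted binary data.

    Builds the maximum-weight spanning tree on pairwise mutual information
    computed from Laplace-smoothed, weight-accumulated 2x2 joint tables, then
    fills the edge conditionals from the same tables.  Root is neuron 0.
    """
    xf = x.astype(np.float64)
    wtot = float(weights.sum())
    if wtot <= 0:
        raise ValueError("zero total weight")
    mu = (weights @ xf) / wtot
    m11 = (xf * weights[:, None]).T @ xf / wtot
    # smoothed cell probabilities of each pair's 2x2 table
    denom = wtot + 4 * laplace
    c11 = (m11 * wtot + laplace) / denom
    c10 = (np.add.outer(mu, -mu * 0) * wtot - m11 * wtot + laplace) / denom
    c10 = ((mu[:, None] - m11) * wtot + laplace) / denom
    c01 = ((mu[None, :] - m11) * wtot + laplace) / denom
    c00 = ((1 - mu[:, None] - mu[None, :] + m11) * wtot + laplace) / denom
    pi1 = (mu * wtot + 2 * laplace) / denom
    pi0 = 1.0 - pi1
    n = mu.size

    def _mi_term(pab, pa, pb):
        return pab * (np.log(pab) - np.log(np.outer(pa, pb)))

    mi = (_mi_term(c11, pi1, pi1) + _mi_term(c10, pi1, pi0)
          + _mi_term(c01, pi0, pi1) + _mi_term(c00, pi0, pi0))
    np.fill_diagonal(mi, 0.0)
    if n == 1:
        parent = np.array([-1])
    else:
        tree = minimum_spanning_tree(-(mi + 1e-12))
        adj = ((tree + tree.T) != 0)
        order, pred = breadth_first_order(adj, 0, directed=False)
        parent = np.asarray(pred, dtype=np.int64)
        parent[0] = -1
    tab = np.empty((n, 2, 2))
    for i in range(n):
        p = parent[i]
        if p < 0:
            tab[i, 0, 1] = tab[i, 1, 1] = np.log(pi1[i])
            tab[i, 0, 0] = tab[i, 1, 0] = np.log(pi0[i])
        else:
            # P(r_i | r_p) from the (i, p) joint
            p11, p10 = c11[i, p], c10[i, p]   # r_i=1, r_p in {1,0}
            p01, p00 = c01[i, p], c00[i, p]
            tab[i, 1, 1] = np.log(p11 / (p11 + p01))
            tab[i, 1, 0] = np.log(p01 / (p11 + p01))
            tab[i, 0, 1] = np.log(p10 / (p10 + p00))
            tab[i, 0, 0] = np.log(p00 / (p10 + p00))
    return TreeMode(parent, tab)


# ---------------------------------------------------------------------------
# the HMM
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(logb, logA, logpi):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    B, M = logb.shape
    b = np.empty((B, M))
    for t in range(B):
        mx = logb[t].max()
        for a in range(M):
            b[t, a] = np.exp(logb[t, a] - mx)
    A = np.exp(logA)
    pi = np.exp(logpi)
    alpha = np.empty((B, M))
    scale = np.empty(B)
    ll = 0.0
    for a in range(M):
        alpha[0, a] = pi[a] * b[0, a]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, B):
        for a in range(M):
            s = 0.0
            for c in range(M):
                s += alpha[t - 1, c] * A[c, a]
            alpha[t, a] = s * b[t, a]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    for t in range(B):
        ll += np.log(scale[t]) + logb[t].max()
    beta = np.empty((B, M))
    beta[B - 1] = 1.0
    gamma = np.empty((B, M))
    xi = np.zeros((M, M))
    gamma[B - 1] = alpha[B - 1] * beta[B - 1]
    gamma[B - 1] /= gamma[B - 1].sum()
    for t in range(B - 2, -1, -1):
        for c in range(M):
            s = 0.0
            for a in range(M):
                s += A[c, a] * b[t + 1, a] * beta[t + 1, a]
            beta[t, c] = s / scale[t + 1]
        g = alpha[t] * beta[t]
        gamma[t] = g / g.sum()
        # transition posteriors
        z = 0.0
        for c in range(M):
            for a in range(M):
                z += alpha[t, c] * A[c, a] * b[t + 1, a] * beta[t + 1, a]
        for c in range(M):
            for a in range(M):
                xi[c, a] += alpha[t, c] * A[c, a] * b[t + 1, a] \
                    * beta[t + 1, a] / z
    return ll, gamma, xi


@dataclass
class TreeHMM:
    """M tree-emission modes, mixture weights and Markov transitions."""

    modes: list
    w: np.ndarray                 # mixture (occupancy) weights
    transitions: np.ndarray       # (M, M) row-stochastic
    startprob: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if not np.isclose(self.w.sum(), 1.0):
            raise ValueError("mode weights must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if self.startprob is None:
            self.startprob = self.w.copy()

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def n_neurons(self) -> int:
        return self.modes[0].n_neurons

    def emission_logprobs(self, x: np.ndarray) -> np.ndarray:
        """(B, M) matrix of log Q_alpha(R_t)."""
        return np.column_stack([m.log_prob(x) for m in self.modes])

    def log_likelihood(self, raster: BinaryRaster) -> float:
        x = raster.values.T
        logb = self.emission_logprobs(x)
        ll, _, _ = _forward_backward(logb, np.log(self.transitions + 1e-300),
                                     np.log(self.startprob + 1e-300))
        return float(ll)

    def marginal_log_prob(self, patterns: np.ndarray) -> np.ndarray:
        """Static mixture log P(R) = log sum_alpha w_alpha Q_alpha(R)."""
        x = np.atleast_2d(patterns)
        logb = self.emission_logprobs(x) + np.log(self.w + 1e-300)
        mx = logb.max(axis=1, keepdims=True)
        return (mx[:, 0] + np.log(np.exp(logb - mx).sum(axis=1)))

    # -- serialization ------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("w", data=self.w, track_times=False)
            f.create_dataset("A", data=self.transitions, track_times=False)
            f.create_dataset("startprob", data=self.startprob,
                             track_times=False)
            f.create_dataset("parents",
                             data=np.stack([m.parent for m in self.modes]),
                             track_times=False)
            f.create_dataset("log_tables",
                             data=np.stack([m.log_table for m in self.modes]),
                             track_times=False)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TreeHMM":
        with h5py.File(path, "r") as f:
            parents = f["parents"][...]
            tables = f["log_tables"][...]
            modes = [TreeMode(parents[k], tables[k])
                     for k in range(parents.shape[0])]
            return cls(modes, f["w"][...], f["A"][...], f["startprob"][...])


DEFAULT_EM = dict(max_iters=100, tol=1e-4, n_restarts=5, laplace=LAPLACE,
                  trans_pseudo=1e-2, mass_floor=1.0, kmeans_iters=5)


def _hamming_seed_labels(x: np.ndarray, M: int,
                         rng: np.random.Generator, iters: int) -> np.ndarray:
    """k-means-style seeding on pattern space with Hamming distance."""
    B = x.shape[0]
    centers = x[rng.choice(B, M, replace=False)].astype(np.float64)
    labels = np.zeros(B, dtype=np.int64)
    for _ in range(iters):
        d = np.abs(x[:, None, :] - centers[None, :, :]).sum(axis=2) \
            if B * M * x.shape[1] < 5e7 else None
        if d is None:
            # blockwise distance for big rasters
            d = np.empty((B, M))
            for k in range(M):
                d[:, k] = np.abs(x - centers[k]).sum(axis=1)
        labels = d.argmin(axis=1)
        for k in range(M):
            sel = labels == k
            if sel.any():
                centers[k] = x[sel].mean(axis=0)
            else:
                centers[k] = x[rng.integers(B)]
    return labels


def _m_step(x, gamma, xi, cfg):
    B, M = gamma.shape
    w = gamma.mean(axis=0)
    w /= w.sum()
    A = xi + cfg["trans_pseudo"]
    A /= A.sum(axis=1, keepdims=True)
    modes = [chow_liu(x, gamma[:, k], cfg["laplace"]) for k in range(M)]
    start = gamma[0] / gamma[0].sum()
    return TreeHMM(modes, w, A, start)


def fit(raster: BinaryRaster, M: int, em_config: dict | None = None,
        seed: int = 0) -> TreeHMM:
    """EM fit of the M-mode tree-emission HMM (best of several restarts).

    E-step: forward-backward over the mode chain.  M-step: reweighted mixture
    weights and transitions, plus a fresh Chow-Liu tree per mode from
    posterior-weighted statistics.  The training log-likelihood is asserted
    non-decreasing (up to smoothing-induced slack); a mode whose posterior
    mass falls below ``mass_floor`` is reseeded once, then dropped with a
    warning.  Deterministic for fixed (data, seed).
    """
    cfg = dict(DEFAULT_EM)
    if em_config:
        cfg.update(em_config)
    if M < 1:
        raise ValueError("M must be >= 1")
    x = np.ascontiguousarray(raster.values.T, dtype=np.uint8)
    B = x.shape[0]
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < M:
        raise ValueError("fewer distinct patterns than modes")
    ss = np.random.SeedSequence(seed)
    best: TreeHMM | None = None
    best_ll = -np.inf
    for r, child in enumerate(ss.spawn(cfg["n_restarts"])):
        rng = np.random.default_rng(child)
        labels = _hamming_seed_labels(x, M, rng, cfg["kmeans_iters"])
        gamma = np.zeros((B, M))
        gamma[np.arange(B), labels] = 1.0
        gamma = 0.9 * gamma + 0.1 / M
        counts = np.zeros((M, M)) + 1.0
        for a, b in zip(labels[:-1], labels[1:]):
            counts[a, b] += 1
        model = _m_step(x, gamma, counts, cfg)
        ll_hist: list[float] = []
        reseeded = False
        for it in range(cfg["max_iters"]):
            logb = model.emission_logprobs(x)
            ll, gamma, xi = _forward_backward(
                logb, np.log(model.transitions + 1e-300),
                np.log(model.startprob + 1e-300))
            if ll_hist and ll < ll_hist[-1] - 1e-6 * max(1.0, abs(ll)):
                logger.warning("EM log-likelihood decreased at iter %d "
                               "(%.6g -> %.6g); stopping restart", it,
                               ll_hist[-1], ll)
                break
            mass = gamma.sum(axis=0)
            if (mass < cfg["mass_floor"]).any():
                dead = np.flatnonzero(mass < cfg["mass_floor"])
                if not reseeded:
                    reseeded = True
                    for k in dead:
                        j = rng.integers(B)
                        gamma[j] = 0.0
                        gamma[j, k] = 1.0
                else:
                    keep = np.flatnonzero(mass >= cfg["mass_floor"])
                    logger.warning("dropping %d empty mode(s); M -> %d",
                                   dead.size, keep.size)
                    gamma = gamma[:, keep]
                    gamma /= gamma.sum(axis=1, keepdims=True)
                    xi = xi[np.ix_(keep, keep)]
                    M_eff = keep.size
                    model = _m_step(x, gamma, xi, cfg)
                    ll_hist = []
                    continue
            model = _m_step(x, gamma, xi, cfg)
            converged = bool(ll_hist) and abs(ll - ll_hist[-1]) < cfg["tol"]
            ll_hist.append(float(ll))
            if converged:
                break
        final_ll = model.log_likelihood(raster)
        if final_ll > best_ll:
            best_ll = final_ll
            model.diagnostics = {"ll_history": ll_hist, "restart": r,
                                 "final_ll": final_ll}
            best = model
    assert best is not None
    return best


def select_num_modes(raster: BinaryRaster, M_grid, cv_config: dict | None = None,
                     seed: int = 0):
    """Choose the number of modes by cross-validated likelihood.

    Contiguous 2/3 train / 1/3 test split (respecting temporal dependence).
    The selected M* is the smallest M whose mean per-bin test log-likelihood
    is within one blocked standard error of the best — the parsimony
    tie-break that returns M*=1 on structureless data.  Returns
    ``(M_star, table)`` with per-M test likelihoods.
    """
    cfg = dict(train_frac=2 / 3, n_blocks=10, em_config=None)
    if cv_config:
        cfg.update(cv_config)
    M_grid = sorted(set(int(m) for m in M_grid))
    if not M_grid:
        raise ValueError("M_grid must be non-empty")
    B = raster.n_bins
    split = int(B * cfg["train_frac"])
    train = BinaryRaster(raster.values[:, :split], raster.bin_width,
                         raster.neuron_ids)
    test = BinaryRaster(raster.values[:, split:], raster.bin_width,
                        raster.neuron_ids)
    rows = []
    ss = np.random.SeedSequence(seed)
    for M, child in zip(M_grid, ss.spawn(len(M_grid))):
        model = fit(train, M, cfg["em_config"],
                    seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))
        # blocked per-bin test log-likelihood
        blocks = np.array_split(np.arange(test.n_bins), cfg["n_blocks"])
        bl = []
        for idx in blocks:
            sub = BinaryRaster(test.values[:, idx], raster.bin_width)
            bl.append(model.log_likelihood(sub) / idx.size)
        rows.append({"M": M, "test_ll_per_bin": float(np.mean(bl)),
                     "se": float(np.std(bl) / np.sqrt(len(bl))),
                     "train_ll_per_bin": model.diagnostics["final_ll"] / split})
    table = pd.DataFrame(rows)
    best = table["test_ll_per_bin"].max()
    best_se = float(table.loc[table["test_ll_per_bin"].idxmax(), "se"])
    ok = table["test_ll_per_bin"] >= best - best_se
    M_star = int(table.loc[ok, "M"].min())
    return M_star, table


# ---------------------------------------------------------------------------
# cluster assignment and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClusterLabels:
    """Per-bin MAP mode labels (0-based) with the posterior over modes."""

    labels: np.ndarray
    posterior: np.ndarray
    dynamic: bool = False

    @property
    def n_modes(self) -> int:
        return self.posterior.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"bin": np.arange(self.labels.size),
                      "label": self.labels,
                      "posterior_max": self.posterior.max(axis=1)}
                     ).to_csv(path, index=False)


def assign(model: TreeHMM, raster: BinaryRaster,
           use_dynamics: bool = False) -> ClusterLabels:
    """MAP cluster per bin.

    Static (default): ``alpha*_t = argmax_alpha w_alpha Q_alpha(R_t)``.
    Dynamic: greedy one-step filter ``argmax P(alpha_t | R_t, alpha_{t-1})``
    with the transition row of the previously assigned mode.  Ties break to
    the lowest mode index.
    """
    x = raster.values.T
    logb = model.emission_logprobs(x)
    if not use_dynamics:
        score = logb + np.log(model.w + 1e-300)
    else:
        score = np.empty_like(logb)
        score[0] = logb[0] + np.log(model.w + 1e-300)
        prev = int(score[0].argmax())
        logA = np.log(model.transitions + 1e-300)
        for t in range(1, len(logb)):
            score[t] = logb[t] + logA[prev]
            prev = int(score[t].argmax())
    mx = score.max(axis=1, keepdims=True)
    post = np.exp(score - mx)
    post /= post.sum(axis=1, keepdims=True)
    return ClusterLabels(score.argmax(axis=1), post, use_dynamics)


def reliability_across_repeats(labels_per_repeat) -> tuple[np.ndarray, float]:
    """Per-bin fraction of repeats agreeing with the modal label.

    Returns ``(per_bin_agreement, mean_agreement)``.  A single repeat is
    degenerate (agreement 1 by definition) and is flagged with a warning.
    """
    L = np.vstack([np.asarray(l) for l in labels_per_repeat])
    R, B = L.shape
    if R == 1:
        logger.warning("single repeat: agreement trivially 1.0")
        return np.ones(B), 1.0
    agree = np.empty(B)
    for t in range(B):
        _, counts = np.unique(L[:, t], return_counts=True)
        agree[t] = counts.max() / R
    return agree, float(agree.mean())


@dataclass
class SeparationReport:
    """Pairwise LDA d' between clusters: d' = |mu1 - mu2| / (sd1 + sd2)."""

    table: pd.DataFrame           # pair-level rows
    directions: dict              # (a, b) -> discriminant vector
    min_dprime_per_cluster: dict
    min_dprime: float


def _pair_dprime(xa: np.ndarray, xb: np.ndarray):
    X = np.vstack([xa, xb]).astype(float)
    y = np.r_[np.zeros(len(xa)), np.ones(len(xb))]
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(X, y)
    wvec = lda.coef_[0]
    pa, pb = xa @ wvec, xb @ wvec
    mu1, mu2 = pa.mean(), pb.mean()
    sd1 = pa.std(ddof=1) if len(pa) > 1 else 0.0
    sd2 = pb.std(ddof=1) if len(pb) > 1 else 0.0
    denom = sd1 + sd2
    d = abs(mu1 - mu2) / denom if denom > 0 else 0.0
    return d, wvec, (mu1, mu2, sd1, sd2)


def separation(raster: BinaryRaster, labels: np.ndarray,
               pairs="all") -> SeparationReport:
    """LDA separation of every cluster pair in pattern space.

    The discriminant direction uses a shrinkage-regularized within-class
    covariance (never singular); d' is the difference of projected means
    divided by the sum of the projected standard deviations.
    """
    labels = np.asarray(labels)
    x = raster.values.T
    present = [k for k in np.unique(labels) if (labels == k).sum() >= 2]
    if pairs == "all":
        pairs = [(a, b) for i, a in enumerate(present)
                 for b in present[i + 1:]]
    rows, dirs = [], {}
    for a, b in pairs:
        xa, xb = x[labels == a], x[labels == b]
        d, wvec, (m1, m2, s1, s2) = _pair_dprime(xa, xb)
        rows.append({"cluster_a": int(a), "cluster_b": int(b), "dprime": d,
                     "mu_a": m1, "mu_b": m2, "sd_a": s1, "sd_b": s2})
        dirs[(int(a), int(b))] = wvec
    table = pd.DataFrame(rows)
    per_cluster = {}
    for k in present:
        sel = (table["cluster_a"] == k) | (table["cluster_b"] == k)
        if sel.any():
            per_cluster[int(k)] = float(table.loc[sel, "dprime"].min())
    overall = float(table["dprime"].min()) if len(table) else np.nan
    return SeparationReport(table, dirs, per_cluster, overall)


def permute_mode_neurons(mode: TreeMode, perm: np.ndarray) -> TreeMode:
    """Relabel the neurons of a tree emission by a permutation.

    ``perm[i]`` is the new index of old neuron i; the tree topology moves
    with the labels, so the permuted emission assigns old neuron i's rates
    and conditionals to new neuron ``perm[i]``.
    """
    perm = np.asarray(perm)
    n = mode.n_neurons
    parent = np.full(n, -1, dtype=np.int64)
    table = np.empty_like(mode.log_table)
    for i in range(n):
        parent[perm[i]] = perm[mode.parent[i]] if mode.parent[i] >= 0 else -1
        table[perm[i]] = mode.log_table[i]
    return TreeMode(parent, table)


def shuffle_control(model: TreeHMM, raster: BinaryRaster,
                    labels: np.ndarray, seed: int = 0,
                    n_shuffles: int = 10) -> pd.DataFrame:
    """Null d' distribution after within-cluster firing-rate rearrangement.

    For each shuffle, every mode's emission distribution has its neuron
    identities permuted (independently per mode) — each cluster keeps its
    multiset of firing rates but the neurons that carry them are scrambled —
    and the rest of the estimation is re-run: bins are re-assigned under the
    shuffled model and all pairwise d' values recomputed on the data.  When
    a mode's emission is neuron-symmetric the permutation leaves the model
    invariant, so the control is an exact no-op there.  Returns the pooled
    pair-level d' table with one block per shuffle.
    """
    labels = np.asarray(labels)
    ss = np.random.SeedSequence(seed)
    rows = []
    for s, child in enumerate(ss.spawn(n_shuffles)):
        rng = np.random.default_rng(child)
        modes = [permute_mode_neurons(m, rng.permutation(model.n_neurons))
                 for m in model.modes]
        shuffled = TreeHMM(modes, model.w, model.transitions,
                           model.startprob)
        new_labels = assign(shuffled, raster).labels
        rep = separation(raster, new_labels)
        for _, r in rep.table.iterrows():
            rows.append({"shuffle": s, **r.to_dict()})
    return pd.DataFrame(rows)


def cluster_triggered_average(movie: StimulusMovie, labels: np.ndarray,
                              lag: int = 0) -> dict[int, np.ndarray]:
    """Mean stimulus frame ``lag`` bins before each cluster's occurrences."""
    labels = np.asarray(labels)
    if movie.n_bins != labels.size:
        raise ValueError("movie and labels length mismatch")
    out = {}
    frames = movie.frames.astype(float)
    for k in np.unique(labels):
        t = np.flatnonzero(labels == k)
        t = t[t - lag >= 0]
        out[int(k)] = frames[:, t - lag].mean(axis=1) if t.size else \
            np.zeros(frames.shape[0])
    return out


def cluster_information(labels_per_repeat, min_repeats_warn: int = 10) -> float:
    """Plug-in mutual information I(cluster; bin index) in bits.

    Treats the bin index as a uniformly distributed stimulus variable and
    estimates P(alpha | t) across repeats.  The plug-in estimator is biased
    upward for few repeats; a warning is logged below ``min_repeats_warn``.
    """
    L = np.vstack([np.asarray(l) for l in labels_per_repeat])
    R, B = L.shape
    if R < min_repeats_warn:
        logger.warning("only %d repeats: plug-in information estimate is "
                       "biased upward", R)
    vals = np.unique(L)
    pj = np.zeros((B, vals.size))
    for j, v in enumerate(vals):
        pj[:, j] = (L == v).mean(axis=0)
    pa = pj.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(pj > 0, pj * np.log2(pj), 0.0).sum(axis=1)
    h_cond = -t1.mean()
    h_marg = float(-(pa[pa > 0] * np.log2(pa[pa > 0])).sum())
    return float(h_marg - h_cond)
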