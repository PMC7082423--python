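"""Pairwise maximum-entropy (inverse Ising) models of binary population activity.

The model over patterns ``R = (r_1..r_N)``, r_i in {0,1}, is

    P(R) = exp(sum_i h_i r_i + sum_{i<j} J_ij r_i r_j) / Z,

the maximum-entropy distribution matching observed rates and pairwise second
moments.  Writing the exponent as ``-E(R)`` makes the model a Boltzmann
distribution at effective temperature T = 1; the family ``P(R; T) \\propto
exp(-E(R)/T)`` is the diagnostic knob used by :mod:`popglass.thermo`.

Fitting is exact (full enumeration, convex maximum likelihood) up to
``EXACT_N_MAX`` neurons and switches to Monte-Carlo gradient matching
(Boltzmann learning) beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import _gibbs
from .raster import PairwiseStats

logger = logging.getLogger(__name__)

EXACT_N_MAX = 20  # largest N for full enumeration; beyond this, Monte Carlo

_pattern_cache: dict[int, np.ndarray] = {}


def enumerate_patterns(n: int) -> np.ndarray:
    """All 2^n binary patterns as a float64 (2^n, n) matrix (cached)."""
    if n > EXACT_N_MAX + 5:
        raise ValueError(f"refusing to enumerate 2^{n} patterns")
    if n not in _pattern_cache:
        if len(_pattern_cache) > 3:  # keep the cache small
            _pattern_cache.pop(next(iter(_pattern_cache)))
        codes = np.arange(1 << n, dtype=np.int64)
        _pattern_cache[n] = ((codes[:, None] >> np.arange(n)) & 1).astype(
            np.float64)
    return _pattern_cache[n]


class ConvergenceError(RuntimeError):
    """Raised when a fit fails to reach its tolerance; carries diagnostics."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class MaxEntModel:
    """Fields ``h_i``, symmetric zero-diagonal couplings ``J_ij`` and T."""

    h: np.ndarray
    J: np.ndarray
    T: float = 1.0
    log_Z: float | None = None
    log_Z_method: str = "none"
    log_Z_se: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError("J shape mismatch")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def n_neurons(self) -> int:
        return self.h.size

    # -- energies and probabilities ----------------------------------------
    def energy(self, patterns: np.ndarray) -> np.ndarray | float:
        """E(R) = -sum_i h_i r_i - sum_{i<j} J_ij r_i r_j (batch-friendly)."""
        x = np.atleast_2d(np.asarray(patterns, dtype=float))
        e = -(x @ self.h) - 0.5 * np.einsum("ij,ij->i", x @ self.J, x)
        return e if np.asarray(patterns).ndim == 2 else float(e[0])

    def ensure_log_z(self, seed: int | None = None) -> float:
        """Exact log Z(T) when enumerable, else an AIS estimate."""
        if self.log_Z is not None:
            return self.log_Z
        if self.n_neurons <= EXACT_N_MAX:
            e = self.energy(enumerate_patterns(self.n_neurons))
            self.log_Z = float(logsumexp(-e / self.T))
            self.log_Z_method = "exact"
        else:
            if seed is None:
                seed = 0
            logw = _gibbs.ais_log_z(self.h, self.J, self.T, 1000, 64,
                                    np.int64(seed))
            base = float(np.sum(np.log1p(np.exp(self.h / self.T))))
            self.log_Z = base + float(logsumexp(logw) - np.log(logw.size))
            self.log_Z_se = float(np.std(np.exp(logw - logw.max()))
                                  / np.mean(np.exp(logw - logw.max()))
                                  / np.sqrt(logw.size))
            self.log_Z_method = "ais"
        return self.log_Z

    def log_probability(self, patterns: np.ndarray, seed: int | None = None):
        """log P(R) = -E(R)/T - log Z(T)."""
        lz = self.ensure_log_z(seed=seed)
        return -np.asarray(self.energy(np.atleast_2d(patterns))) / self.T - lz \
            if np.asarray(patterns).ndim == 2 \
            else -self.energy(patterns) / self.T - lz

    def at_temperature(self, T: float) -> "MaxEntModel":
        return MaxEntModel(self.h, self.J, T)

    # -- serialization ------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("h", data=self.h, track_times=False)
            f.create_dataset("J", data=self.J, track_times=False)
            f.attrs["T"] = self.T
            f.attrs["log_Z"] = np.nan if self.log_Z is None else self.log_Z
            f.attrs["log_Z_method"] = self.log_Z_method

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "MaxEntModel":
        with h5py.File(path, "r") as f:
            lz = float(f.attrs["log_Z"])
            return cls(f["h"][...], f["J"][...], float(f.attrs["T"]),
                       None if np.isnan(lz) else lz,
                       str(f.attrs["log_Z_method"]))


def independent_model(rates: np.ndarray) -> MaxEntModel:
    """J = 0 model with h_i = logit(p_i) (exact for independent units)."""
    p = np.asarray(rates, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("independent model needs rates strictly in (0,1)")
    h = np.log(p / (1 - p))
    n = p.size
    m = MaxEntModel(h, np.zeros((n, n)))
    m.log_Z = float(np.sum(np.log1p(np.exp(h))))
    m.log_Z_method = "exact"
    return m


# ---------------------------------------------------------------------------
# exact inference by enumeration
# ---------------------------------------------------------------------------

def exact_moments(h: np.ndarray, J: np.ndarray, T: float = 1.0):
    """Model rates, second moments and log Z by full enumeration."""
    n = h.size
    x = enumerate_patterns(n)
    e = -(x @ h) - 0.5 * np.einsum("ij,ij->i", x @ J, x)
    logw = -e / T
    lz = float(logsumexp(logw))
    p = np.exp(logw - lz)
    mean = p @ x
    m2 = (x * p[:, None]).T @ x
    return mean, m2, lz


def model_entropy_bits(model: MaxEntModel) -> float:
    """Shannon entropy of the pattern distribution (enumerable N only)."""
    x = enumerate_patterns(model.n_neurons)
    lp = np.asarray(model.log_probability(x))
    p = np.exp(lp)
    return float(-(p * lp).sum() / np.log(2))


def _pack(h, J):
    n = h.size
    iu = np.triu_indices(n, 1)
    return np.concatenate([h, J[iu]])


def _unpack(x, n):
    h = x[:n]
    J = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    J[iu] = x[n:]
    J += J.T
    return h, J


def exact_fit(stats: PairwiseStats, tol: float = 1e-6,
              damping: float | None = None, max_iter: int = 2000,
              drop_degenerate: bool = True) -> MaxEntModel:
    """Maximum-likelihood fit by full enumeration (convex, seed-free).

    Matches model rates and second moments to ``stats`` within ``tol``.
    Neurons with rate 0 or 1 are dropped (they carry no constraint); the fit
    then covers the remaining subset, recorded in ``diagnostics['kept']``.
    A small L2 damping on J is applied automatically when any moment sits
    within 1e-3 of its Frechet bound (reported in diagnostics).
    """
    kept = np.arange(stats.n_neurons)
    if stats.degenerate.any():
        if not drop_degenerate:
            raise ValueError("degenerate rates present")
        stats, kept = stats.active_subset()
    n = stats.n_neurons
    if n > EXACT_N_MAX:
        raise ValueError(f"exact_fit limited to N <= {EXACT_N_MAX}")
    stats.check_feasible(strict=True)
    p, m = stats.rates, stats.second_moments
    iu = np.triu_indices(n, 1)
    mu = np.concatenate([p, m[iu]])

    if damping is None:
        lo, hi = stats.frechet_bounds()
        near = min(np.min(m[iu] - lo[iu]), np.min(hi[iu] - m[iu])) < 1e-3 \
            if iu[0].size else False
        damping = 1e-6 if near else 0.0

    def objective(x):
        h, J = _unpack(x, n)
        mean, m2, lz = exact_moments(h, J)
        f = lz - x @ mu + damping * np.sum(J[iu] ** 2)
        g = np.concatenate([mean, m2[iu]]) - mu
        g[n:] += 2 * damping * J[iu]
        return f, g

    x0 = _pack(np.log(p / (1 - p)), np.zeros((n, n)))
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-15,
                            "gtol": 0.1 * tol})
    h, J = _unpack(res.x, n)
    mean, m2, lz = exact_moments(h, J)
    resid = max(np.abs(mean - p).max(),
                np.abs(m2[iu] - m[iu]).max() if iu[0].size else 0.0)
    diag = {"kept": kept, "residual": resid, "damping": damping,
            "n_iter": res.nit, "method": "exact"}
    if resid > tol:
        # polish with a few more iterations from the current point
        res = minimize(objective, res.x, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-16,
                                "gtol": 0.01 * tol})
        h, J = _unpack(res.x, n)
        mean, m2, lz = exact_moments(h, J)
        resid = max(np.abs(mean - p).max(),
                    np.abs(m2[iu] - m[iu]).max() if iu[0].size else 0.0)
        diag["residual"] = resid
    if resid > max(tol, 10 * damping):
        raise ConvergenceError(f"exact_fit residual {resid:.3g} > tol {tol}",
                               diag)
    model = MaxEntModel(h, J, 1.0, lz, "exact", diagnostics=diag)
    return model


# ---------------------------------------------------------------------------
# Monte-Carlo inference (Boltzmann learning)
# ---------------------------------------------------------------------------

def _sample_moments(samples: np.ndarray):
    x = samples.astype(np.float64)
    p = x.mean(axis=0)
    m = (x.T @ x) / x.shape[0]
    np.fill_diagonal(m, p)
    return p, m


DEFAULT_MC_FIT = dict(
    n_samples=2500,      # Gibbs samples per learning iteration
    thin=2,              # sweeps between retained samples
    burn_in=200,         # sweeps before the first sample of each run
    eta0=0.4,            # initial learning rate
    tau=200.0,           # Robbins-Monro decay constant
    max_iters=1200,
    min_iters=300,
    check_every=150,     # convergence checkpoints on the averaged parameters
    tol_se_factor=3.0,   # converged when residuals < factor * MC standard error
    average_last=100,    # Polyak averaging window for the returned parameters
    check_samples=20000, # long run for honest residuals at each checkpoint
    init=None,           # None (J=0) or 'pair' (damped log-odds warm start)
)


def mc_fit(stats: PairwiseStats, fit_config: dict | None = None,
           seed: int = 0, raise_on_fail: bool = True) -> MaxEntModel:
    """Boltzmann learning: iterative moment matching with Gibbs sampling.

    Updates ``(h, J)`` along (data - model) moments with a Robbins-Monro
    decaying step, Polyak-averages the tail of the trajectory, and stops once
    every moment residual is below ``tol_se_factor`` times its Monte-Carlo
    standard error (measured on a final long run).  Fully reproducible given
    ``seed``.
    """
    cfg = dict(DEFAULT_MC_FIT)
    if fit_config:
        cfg.update(fit_config)
    kept = np.arange(stats.n_neurons)
    if stats.degenerate.any():
        stats, kept = stats.active_subset()
    stats.check_feasible(strict=False)
    n = stats.n_neurons
    iu = np.triu_indices(n, 1)
    p_data, m_data = stats.rates, stats.second_moments

    ss = np.random.SeedSequence(seed)
    kernel_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                    for s in ss.spawn(cfg["max_iters"] + 1)]

    h = np.log(np.clip(p_data, 1e-6, 1 - 1e-6)
               / (1 - np.clip(p_data, 1e-6, 1 - 1e-6)))
    if cfg.get("init") == "pair":
        # independent-pair log-odds-ratio approximation: exact for a single
        # pair, an overestimate in a network, but a fast warm start
        pi, pj = p_data[:, None], p_data[None, :]
        m11 = np.clip(m_data, 1e-6, None)
        m10 = np.clip(pi - m_data, 1e-6, None)
        m01 = np.clip(pj - m_data, 1e-6, None)
        m00 = np.clip(1 - pi - pj + m_data, 1e-6, None)
        J = 0.5 * np.log(m11 * m00 / (m10 * m01))
        np.fill_diagonal(J, 0.0)
        J = 0.5 * (J + J.T)
    else:
        J = np.zeros((n, n))
    state = np.zeros(n, dtype=np.float64)
    window: list[tuple[np.ndarray, np.ndarray]] = []
    history = []

    def _averaged():
        ha = np.mean([w[0] for w in window], axis=0)
        Ja = np.mean([w[1] for w in window], axis=0)
        Ja = 0.5 * (Ja + Ja.T)
        np.fill_diagonal(Ja, 0.0)
        return ha, Ja

    def _check(ha, Ja, cseed):
        """Honest residuals on a long fresh run with blocked standard errors."""
        samples = _gibbs.gibbs_sample(ha, Ja, 1.0,
                                      np.int64(cfg["check_samples"]),
                                      np.int64(cfg["burn_in"]),
                                      np.int64(cfg["thin"]), np.int64(cseed))
        p_mod, m_mod = _sample_moments(samples)
        nb = 10
        blocks = np.array_split(samples.astype(float), nb)
        # tolerance is defined at the per-iteration sampling effort: the
        # long run only measures the residual accurately
        scale = np.sqrt(cfg["check_samples"] / cfg["n_samples"])
        se_p = scale * np.std([b.mean(axis=0) for b in blocks],
                              axis=0) / np.sqrt(nb)
        se_m = scale * np.std([(b.T @ b) / len(b) for b in blocks],
                              axis=0) / np.sqrt(nb)
        ok_p = np.abs(p_mod - p_data) <= cfg["tol_se_factor"] * se_p
        dm = np.abs(m_mod - m_data)[iu]
        ok_m = dm <= cfg["tol_se_factor"] * se_m[iu]
        conv = bool(ok_p.all() and (ok_m.all() if iu[0].size else True))
        return conv, float(np.abs(p_mod - p_data).max()), \
            float(dm.max()) if iu[0].size else 0.0

    # burn in the persistent chain once; subsequent iterations resume it
    _gibbs.gibbs_sample_resume(h, J, 1.0, np.int64(1),
                               np.int64(cfg["burn_in"]),
                               np.int64(kernel_seeds[0] ^ 1), state)
    converged = False
    res_p = res_m = np.nan
    for t in range(cfg["max_iters"]):
        samples = _gibbs.gibbs_sample_resume(
            h, J, 1.0, np.int64(cfg["n_samples"]), np.int64(cfg["thin"]),
            np.int64(kernel_seeds[t]), state)
        p_mod, m_mod = _sample_moments(samples)
        gh = p_data - p_mod
        gJ = m_data - m_mod
        np.fill_diagonal(gJ, 0.0)
        eta = cfg["eta0"] / (1.0 + t / cfg["tau"])
        h = h + eta * gh
        J = J + eta * gJ
        resid = max(np.abs(gh).max(), np.abs(gJ[iu]).max() if iu[0].size else 0)
        history.append(resid)
        window.append((h.copy(), J.copy()))
        if len(window) > cfg["average_last"]:
            window.pop(0)
        if (t + 1) >= cfg["min_iters"] and (t + 1) % cfg["check_every"] == 0:
            ha, Ja = _averaged()
            converged, res_p, res_m = _check(ha, Ja, kernel_seeds[-1] ^ t)
            if converged:
                break
    h_fit, J_fit = _averaged()
    if not converged:
        converged, res_p, res_m = _check(h_fit, J_fit, kernel_seeds[-1])
    diag = {"kept": kept, "converged": converged,
            "residual_rates": res_p, "residual_moments": res_m,
            "history": history, "method": "mc"}
    if not converged and raise_on_fail:
        raise ConvergenceError(
            "mc_fit did not reach tolerance: max rate residual "
            f"{diag['residual_rates']:.4g}, max moment residual "
            f"{diag['residual_moments']:.4g}", diag)
    return MaxEntModel(h_fit, J_fit, 1.0, diagnostics=diag)


def pl_fit(raster_values: np.ndarray, l2: float = 1e-4,
           max_iter: int = 500) -> MaxEntModel:
    """Pseudo-likelihood fit: maximize the product of per-site conditionals.

    Consistent for pairwise binary models, deterministic, and fast at large
    N; trades the exact likelihood for per-site logistic regressions with a
    shared symmetric coupling matrix.  ``raster_values`` is the (N, B) binary
    matrix.  A small L2 penalty keeps rarely co-active pairs bounded.
    """
    x = np.asarray(raster_values, dtype=np.float64).T  # B x N
    b, n = x.shape
    iu = np.triu_indices(n, 1)

    def unpack(v):
        h = v[:n]
        J = np.zeros((n, n))
        J[iu] = v[n:]
        J += J.T
        return h, J

    def objective(v):
        h, J = unpack(v)
        f = h[None, :] + x @ J
        val = (-x * f + np.logaddexp(0, f)).sum() / b \
            + l2 * np.sum(v[n:] ** 2)
        p = expit(f)
        d = p - x
        gh = d.mean(axis=0)
        gj = (d.T @ x + x.T @ d) / b
        g = np.concatenate([gh, gj[iu]])
        g[n:] += 2 * l2 * v[n:]
        return val, g

    p0 = np.clip(x.mean(axis=0), 1e-4, 1 - 1e-4)
    v0 = np.zeros(n + iu[0].size)
    v0[:n] = np.log(p0 / (1 - p0))
    res = minimize(objective, v0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12})
    h, J = unpack(res.x)
    return MaxEntModel(h, J, 1.0,
                       diagnostics={"method": "pseudo-likelihood",
                                    "n_iter": res.nit, "n_bins": b})


def fit(stats: PairwiseStats, seed: int = 0, **kwargs) -> MaxEntModel:
    """Dispatch to :func:`exact_fit` (N <= 20) or :func:`mc_fit` (N > 20)."""
    n_eff = int((~stats.degenerate).sum())
    if n_eff <= EXACT_N_MAX:
        kwargs.pop("fit_config", None)
        return exact_fit(stats, **kwargs)
    return mc_fit(stats, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# coupling / correlation scaling
# ---------------------------------------------------------------------------

def scale_couplings(model: MaxEntModel, factor: float, stats: PairwiseStats,
                    tol: float = 1e-6, seed: int = 0) -> MaxEntModel:
    """Scale J -> factor*J and refit the fields so rates match ``stats``.

    The interaction-scaling manipulation: correlations strengthen or weaken
    with ``factor`` while every neuron keeps its observed firing rate.
    """
    if factor < 0:
        raise ValueError("factor must be non-negative")
    p = stats.rates[~stats.degenerate] if stats.degenerate.any() else stats.rates
    J2 = factor * model.J
    n = model.n_neurons
    if p.size != n:
        raise ValueError("stats do not match model size")
    if factor == 0.0:
        return independent_model(p)
    if n <= EXACT_N_MAX:
        def objective(h):
            mean, _, lz = exact_moments(h, J2)
            return lz - h @ p, mean - p
        res = minimize(objective, model.h, jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000, "ftol": 1e-15,
                                "gtol": 0.1 * tol})
        mean, _, lz = exact_moments(res.x, J2)
        if np.abs(mean - p).max() > tol:
            raise ConvergenceError("rate refit failed in scale_couplings",
                                   {"residual": float(np.abs(mean - p).max())})
        return MaxEntModel(res.x, J2, 1.0, lz, "exact")
    # stochastic approximation on h only
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(401)]
    h = model.h.copy()
    state = np.zeros(n)
    h_avg, n_avg = np.zeros_like(h), 0
    for t in range(400):
        samples = _gibbs.gibbs_sample_resume(h, J2, 1.0, np.int64(1000),
                                             np.int64(2), np.int64(seeds[t]),
                                             state)
        p_mod = samples.mean(axis=0)
        h = h + (0.5 / (1 + t / 100)) * (p - p_mod)
        if t >= 350:
            h_avg += h
            n_avg += 1
    return MaxEntModel(h_avg / n_avg, J2, 1.0)


def scale_correlations(stats: PairwiseStats, gamma: float) -> PairwiseStats:
    """Shrink (or amplify) all pairwise covariances: C_ij -> gamma * C_ij.

    Rates are untouched; second moments are rebuilt from the scaled
    covariances and checked against their Frechet bounds.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = stats.rates
    cov = gamma * stats.covariance
    m = cov + np.outer(p, p)
    np.fill_diagonal(m, p)
    out = PairwiseStats(p, m, stats.n_bins)
    out.check_feasible(strict=False)
    return out
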