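"""Heat capacity, specific-heat scans and the correlation-scaling transition.

For the model family ``P(R; T) \\propto exp(-E(R)/T)`` the heat capacity

    C(T) = d<E>/dT = Var_T(E) / T^2

measures the width of the log-probability distribution; a peak in the
specific heat C/N that grows with population size and sits just above T = 1
is the operational signature of the glassy, marginally sub-critical regime.
The gamma scan shrinks all pairwise covariances by a common factor
``C_ij -> gamma * C_ij``, refits the pairwise model at each gamma, and
locates the transition gamma* as the midpoint of a sigmoid fit to
C(T=1)/N versus gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logsumexp

from . import _gibbs, maxent
from .maxent import EXACT_N_MAX, MaxEntModel
from .raster import BinaryRaster, PairwiseStats, empirical_stats

logger = logging.getLogger(__name__)

DEFAULT_T_GRID = np.geomspace(0.3, 3.0, 50)


def _mc_energy_samples(model: MaxEntModel, T: float, n_samples: int,
                       burn_in: int, thin: int, seed: int) -> np.ndarray:
    s = _gibbs.gibbs_sample(model.h, model.J, float(T), np.int64(n_samples),
                            np.int64(burn_in), np.int64(thin), np.int64(seed))
    return np.asarray(model.energy(s.astype(np.float64)))


DEFAULT_MC_THERMO = dict(n_samples=4000, burn_in=500, thin=5, n_blocks=20)


def heat_capacity(model: MaxEntModel, T: float = 1.0, method: str = "auto",
                  mc_config: dict | None = None, seed: int = 0):
    """Heat capacity ``C(T) = Var_T(E)/T^2`` with its standard error.

    ``method='exact'`` enumerates all patterns (N <= 20 only);
    ``method='mc'`` estimates Var(E) from Gibbs samples at temperature T,
    with a blocked standard error.  Returns ``(C, se)``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if method == "auto":
        method = "exact" if model.n_neurons <= EXACT_N_MAX else "mc"
    if method == "exact":
        if model.n_neurons > EXACT_N_MAX:
            raise ValueError("exact heat capacity refused for N > "
                             f"{EXACT_N_MAX}")
        e = model.energy(maxent.enumerate_patterns(model.n_neurons))
        logw = -e / T
        p = np.exp(logw - logsumexp(logw))
        mu = float(p @ e)
        var = float(p @ (e - mu) ** 2)
        return var / T**2, 0.0
    cfg = dict(DEFAULT_MC_THERMO)
    if mc_config:
        cfg.update(mc_config)
    e = _mc_energy_samples(model, T, cfg["n_samples"], cfg["burn_in"],
                           cfg["thin"], seed)
    blocks = np.array_split(e, cfg["n_blocks"])
    bvars = np.array([np.var(b) for b in blocks])
    c = float(np.var(e) / T**2)
    se = float(np.std(bvars) / np.sqrt(len(blocks)) / T**2)
    return c, se


def independent_heat_capacity(h: np.ndarray, T: float | np.ndarray):
    """Closed-form C(T) of an independent model: sum_i h_i^2 p_i(1-p_i)/T^2
    with p_i = sigmoid(h_i / T)."""
    T = np.asarray(T, dtype=float)
    p = expit(np.asarray(h)[:, None] / T[None, :] if T.ndim else
              np.asarray(h) / T)
    c = (np.asarray(h)[:, None] ** 2 * p * (1 - p)).sum(axis=0) / T**2 \
        if T.ndim else float((np.asarray(h) ** 2 * p * (1 - p)).sum() / T**2)
    return c


def mean_energy(model: MaxEntModel, T: float) -> float:
    """Exact <E> at temperature T (enumerable N only)."""
    e = model.energy(maxent.enumerate_patterns(model.n_neurons))
    logw = -e / T
    p = np.exp(logw - logsumexp(logw))
    return float(p @ e)


@dataclass
class ThermoScan:
    """C(T) curve over a temperature grid with its interpolated peak."""

    T_grid: np.ndarray
    mean_energy: np.ndarray
    C: np.ndarray
    se: np.ndarray
    n_neurons: int
    method: str
    T_peak: float = field(init=False)

    def __post_init__(self) -> None:
        self.T_peak = parabolic_peak(self.T_grid, self.C)

    @property
    def specific_heat(self) -> np.ndarray:
        return self.C / self.n_neurons


def parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak location by 3-point parabolic interpolation in log x.

    Grid-resolution independent; falls back to the grid argmax at the
    boundary or for single-point grids.
    """
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1 or len(y) < 3:
        return float(x[k])
    lx = np.log(x[k - 1:k + 2])
    yy = y[k - 1:k + 2]
    denom = (yy[0] - 2 * yy[1] + yy[2])
    if denom >= 0:
        return float(x[k])
    shift = 0.5 * (yy[0] - yy[2]) / denom
    return float(np.exp(lx[1] + shift * (lx[2] - lx[1])))


def scan_model(model: MaxEntModel, T_grid=None, method: str = "auto",
               mc_config: dict | None = None, seed: int = 0) -> ThermoScan:
    """C(T) over a temperature grid for one model."""
    T_grid = DEFAULT_T_GRID if T_grid is None else np.asarray(T_grid, float)
    if len(T_grid) > 1 and not (np.diff(T_grid) > 0).all():
        raise ValueError("T_grid must be strictly increasing")
    if method == "auto":
        method = "exact" if model.n_neurons <= EXACT_N_MAX else "mc"
    C = np.empty_like(T_grid)
    se = np.zeros_like(T_grid)
    me = np.empty_like(T_grid)
    if method == "exact":
        e = model.energy(maxent.enumerate_patterns(model.n_neurons))
        for k, T in enumerate(T_grid):
            logw = -e / T
            p = np.exp(logw - logsumexp(logw))
            mu = float(p @ e)
            me[k] = mu
            C[k] = float(p @ (e - mu) ** 2) / T**2
    else:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                 for s in ss.spawn(len(T_grid))]
        cfg = dict(DEFAULT_MC_THERMO)
        if mc_config:
            cfg.update(mc_config)
        for k, T in enumerate(T_grid):
            e = _mc_energy_samples(model, T, cfg["n_samples"], cfg["burn_in"],
                                   cfg["thin"], seeds[k])
            me[k] = float(np.mean(e))
            C[k] = float(np.var(e)) / T**2
            blocks = np.array_split(e, cfg["n_blocks"])
            se[k] = float(np.std([np.var(b) for b in blocks])
                          / np.sqrt(len(blocks))) / T**2
    return ThermoScan(T_grid, me, C, se, model.n_neurons, method)


def specific_heat_scan(model: MaxEntModel, T_grid=None,
                       subset_sizes=(10, 20, 40), n_subsets: int = 5,
                       seed: int = 0, n_stat_bins: int = 40000,
                       raster: BinaryRaster | None = None,
                       fit_tol: float = 1e-5, nested: bool = True,
                       large_n_backend: str = "pl",
                       mc_fit_config: dict | None = None,
                       mc_thermo_config: dict | None = None) -> list[ThermoScan]:
    """Size dependence of the specific heat: refit random subpopulations.

    For each size, draws ``n_subsets`` random neuron subsets, refits a
    pairwise model to each subset's marginal statistics (measured on a raster
    sampled from ``model``, or on ``raster`` if given), scans C(T), and
    averages the curves.  With ``nested=True`` (default) the subsets of
    growing size are nested within one random ordering per draw, which pairs
    the size comparison and cancels much of the subset-composition
    variability.  Returns one :class:`ThermoScan` per size; the peak
    temperatures T* trace the size trend.

    Subsets up to the enumeration limit are refit by exact maximum
    likelihood; larger subsets use the ``large_n_backend``:
    pseudo-likelihood (``'pl'``, default — deterministic and free of the
    slow-mode shrinkage that stochastic moment matching leaves in weakly
    constrained coupling directions, which would bias T* upward) or
    Boltzmann learning (``'mc'``).
    """
    from .synth import sample_ising

    T_grid = DEFAULT_T_GRID if T_grid is None else np.asarray(T_grid, float)
    ss = np.random.SeedSequence(seed)
    s_raster, s_subsets, s_fit, s_scan = ss.spawn(4)
    if raster is None:
        raster = sample_ising(model, n_stat_bins,
                              seed=int(s_raster.generate_state(1)[0]
                                       & 0x7FFFFFFF))
    rng = np.random.default_rng(s_subsets)
    fit_seeds = iter([int(s.generate_state(1)[0] & 0x7FFFFFFF)
                      for s in s_fit.spawn(len(subset_sizes) * n_subsets)])
    scan_seeds = iter([int(s.generate_state(1)[0] & 0x7FFFFFFF)
                       for s in s_scan.spawn(len(subset_sizes) * n_subsets)])
    orders = [rng.permutation(raster.n_neurons) for _ in range(n_subsets)]
    scans = []
    for size in subset_sizes:
        if size > raster.n_neurons:
            raise ValueError("subset size exceeds population")
        curves, energies = [], []
        # the full population admits only one subset
        n_sub = 1 if size == raster.n_neurons else n_subsets
        for k in range(n_sub):
            idx = np.sort(orders[k][:size]) if nested else \
                np.sort(rng.choice(raster.n_neurons, size, replace=False))
            sub_raster = raster.subset(idx)
            stats = empirical_stats(sub_raster)
            fseed = next(fit_seeds)
            if int((~stats.degenerate).sum()) <= EXACT_N_MAX:
                sub = maxent.exact_fit(stats, tol=fit_tol)
            elif large_n_backend == "pl":
                sub = maxent.pl_fit(sub_raster.values)
            else:
                sub = maxent.mc_fit(stats, mc_fit_config, seed=fseed,
                                    raise_on_fail=False)
            s = scan_model(sub, T_grid, mc_config=mc_thermo_config,
                           seed=next(scan_seeds))
            curves.append(s.C)
            energies.append(s.mean_energy)
        C = np.mean(curves, axis=0)
        se = np.std(curves, axis=0) / np.sqrt(n_sub)
        scans.append(ThermoScan(T_grid, np.mean(energies, axis=0), C, se,
                                size, "subset-average"))
    return scans


# ---------------------------------------------------------------------------
# correlation-scaling (gamma) transition
# ---------------------------------------------------------------------------

@dataclass
class GammaScan:
    """C(T=1) versus correlation shrinkage gamma, with the sigmoid midpoint."""

    gamma_grid: np.ndarray
    C_at_T1: np.ndarray            # heat capacity at T=1 per gamma
    specific_heat_at_T1: np.ndarray
    n_neurons: int
    sigmoid_params: dict | None
    gamma_star: float
    degenerate: bool
    valid: np.ndarray


def fit_sigmoid(x: np.ndarray, y: np.ndarray):
    """4-parameter logistic least-squares fit; returns (params, midpoint).

    ``y = base + amplitude / (1 + exp(-(x - midpoint)/width))``; the
    midpoint is constrained to the hull of ``x``.  Raises RuntimeError when
    the curve carries no resolvable transition.
    """

    def logistic(x, base, amp, mid, width):
        return base + amp / (1 + np.exp(-(x - mid) / width))

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    span = y.max() - y.min()
    if span <= 0:
        raise RuntimeError("flat curve: no transition")
    p0 = [y.min(), span, float(x[np.argmin(np.abs(y - y.mean()))]),
          0.25 * (x.max() - x.min())]
    bounds = ([-np.inf, -np.inf, x.min(), 1e-4],
              [np.inf, np.inf, x.max(), 10 * (x.max() - x.min())])
    popt, _ = curve_fit(logistic, x, y, p0=p0, bounds=bounds, maxfev=20000)
    params = dict(zip(("base", "amplitude", "midpoint", "width"), popt))
    return params, float(popt[2])


def gamma_transition(stats: PairwiseStats, gamma_grid=None,
                     fit_backend: str = "auto", seed: int = 0,
                     fit_tol: float = 1e-5,
                     mc_fit_config: dict | None = None,
                     mc_thermo_config: dict | None = None) -> GammaScan:
    """Locate the correlation strength gamma* where the clustered regime is lost.

    For each gamma: shrink covariances, refit the pairwise model to the
    scaled moments, and record C(T=1)/N; then fit a 4-parameter logistic in
    gamma and report its midpoint as gamma*.  Individual fit failures flag
    the point; the sigmoid fit proceeds if >= 5 points remain.
    """
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, 1.0, 11)
    gamma_grid = np.asarray(gamma_grid, float)
    if gamma_grid.min() < 0 or gamma_grid.max() > 1:
        raise ValueError("gamma_grid must lie in [0, 1]")
    if 0.0 not in gamma_grid or 1.0 not in gamma_grid:
        raise ValueError("gamma_grid must include 0 and 1")
    n_eff = int((~stats.degenerate).sum())
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
             for s in ss.spawn(2 * len(gamma_grid))]
    C = np.full_like(gamma_grid, np.nan)
    valid = np.zeros(len(gamma_grid), dtype=bool)
    for k, g in enumerate(gamma_grid):
        try:
            scaled = maxent.scale_correlations(stats, g)
            if fit_backend == "exact" or (fit_backend == "auto"
                                          and n_eff <= EXACT_N_MAX):
                m = maxent.exact_fit(scaled, tol=fit_tol)
            else:
                m = maxent.mc_fit(scaled, mc_fit_config, seed=seeds[2 * k],
                                  raise_on_fail=False)
            c, _ = heat_capacity(m, 1.0, mc_config=mc_thermo_config,
                                 seed=seeds[2 * k + 1])
            C[k] = c
            valid[k] = True
        except (ValueError, maxent.ConvergenceError) as err:
            logger.warning("gamma=%.3g point failed: %s", g, err)
    if valid.sum() < 5:
        raise RuntimeError("too few valid gamma points for a sigmoid fit")
    degenerate = False
    params: dict | None = None
    gamma_star = np.nan
    try:
        params, gamma_star = fit_sigmoid(gamma_grid[valid], C[valid])
        # a transition needs a resolvable amplitude relative to the curve
        if abs(params["amplitude"]) < 0.05 * max(np.nanmax(C), 1e-12):
            degenerate = True
    except RuntimeError:
        degenerate = True
    if degenerate:
        logger.warning("gamma scan is flat: sigmoid fit flagged degenerate")
    return GammaScan(gamma_grid, C, C / max(n_eff, 1), n_eff, params,
                     gamma_star, degenerate, valid)


# ---------------------------------------------------------------------------
# cluster-distribution temperature transform
# ---------------------------------------------------------------------------

@dataclass
class ClusterDistribution:
    """P_T(alpha) over clusters after the temperature transform, with entropy."""

    probabilities: np.ndarray
    T: float
    entropy_bits: float


def temper_cluster_distribution(p: np.ndarray, T: float) -> ClusterDistribution:
    """Temperature transform of a cluster distribution.

    ``P_T(alpha) = P(alpha)^{1/T} / sum_beta P(beta)^{1/T}``; zero-probability
    clusters are excluded from the support.  T -> 0 concentrates all weight on
    the most common cluster; T -> inf flattens toward uniform.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    p = np.asarray(p, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must be a probability vector")
    out = np.zeros_like(p)
    sup = p > 0
    logp = np.log(p[sup]) / T
    out[sup] = np.exp(logp - logsumexp(logp))
    s = float(-(out[out > 0] * np.log2(out[out > 0])).sum())
    return ClusterDistribution(out, T, s)
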