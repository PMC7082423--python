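"""Canonical study-condition experiments, shared by the analysis drivers,
the test suite and the acceptance script.

Each function runs one complete experiment at its stated conditions from a
single seed and returns plain numbers/tables; nothing here reads external
data.
"""

from __future__ import annotations

import numpy as np

from . import maxent, synth, thermo, treehmm

# conditions of the planted-mode separation experiment: M = 5 well-separated
# modes with disjoint 8-neuron active sets over N = 40 neurons, in-set
# emission probability 0.5 versus 0.01 outside, 20,000 bins
DPRIME_CONDITIONS = dict(n_neurons=40, n_modes=5, active_size=8, p_in=0.5,
                         p_out=0.01, self_transition=0.75, n_bins=20000)


def min_dprime_experiment(seed: int = 0, n_bins: int | None = None,
                          em_config: dict | None = None) -> dict:
    """Fit the tree-HMM to the planted-mode raster and measure separation.

    Generates the raster, fits the M=5 tree-emission HMM, MAP-assigns every
    bin, computes the regularized two-class LDA d' for all cluster pairs and
    returns the minimum together with the full pair table and the
    permutation-aligned label recovery.
    """
    cond = dict(DPRIME_CONDITIONS)
    if n_bins is not None:
        cond["n_bins"] = n_bins
    ss = np.random.SeedSequence(seed)
    s_truth, s_raster, s_fit = [int(c.generate_state(1)[0] & 0x7FFFFFFF)
                                for c in ss.spawn(3)]
    truth = synth.make_planted_modes(
        cond["n_neurons"], cond["n_modes"], cond["active_size"],
        cond["p_in"], cond["p_out"], cond["self_transition"], seed=s_truth)
    raster, true_labels = synth.sample_mode_raster(truth, cond["n_bins"],
                                                   seed=s_raster)
    em = dict(n_restarts=3, max_iters=60)
    if em_config:
        em.update(em_config)
    model = treehmm.fit(raster, cond["n_modes"], em, seed=s_fit)
    labels = treehmm.assign(model, raster)
    sep = treehmm.separation(raster, labels.labels)
    acc = aligned_accuracy(true_labels, labels.labels, cond["n_modes"])
    return {"min_dprime": sep.min_dprime, "pair_table": sep.table,
            "label_accuracy": acc, "n_bins": cond["n_bins"],
            "model": model, "raster": raster, "labels": labels.labels,
            "true_labels": true_labels, "truth": truth}


def aligned_accuracy(true_labels: np.ndarray, pred_labels: np.ndarray,
                     n_classes: int) -> float:
    """Label agreement after the optimal label permutation (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((n_classes, n_classes))
    for a, b in zip(np.asarray(true_labels), np.asarray(pred_labels)):
        conf[int(a), int(b)] += 1
    ri, ci = linear_sum_assignment(-conf)
    return float(conf[ri, ci].sum() / len(true_labels))


# the frustrated ensemble for the size scan: couplings strong enough that the
# full population sits just below its specific-heat peak (T* > 1) — the
# glassy, marginally sub-critical regime — while small subsets remain
# field-dominated with a higher-temperature peak
TREND_CONDITIONS = dict(n_neurons=40, J_std=0.45, h_level=-3.0,
                        subset_sizes=(10, 20, 40), n_subsets=3,
                        n_stat_bins=120000)


def specific_heat_trend(seed: int = 0, n_subsets: int | None = None) -> dict:
    """Specific-heat scans of nested subpopulations of a frustrated model.

    Returns the per-size peak temperatures T* and peak specific heats; under
    the stated conditions T* decreases and the peak C/N grows with N.
    """
    cond = dict(TREND_CONDITIONS)
    if n_subsets is not None:
        cond["n_subsets"] = n_subsets
    ss = np.random.SeedSequence(seed)
    s_model, s_scan = [int(c.generate_state(1)[0] & 0x7FFFFFFF)
                       for c in ss.spawn(2)]
    model = synth.make_frustrated_model(cond["n_neurons"], cond["J_std"],
                                        cond["h_level"], seed=s_model)
    T_grid = np.geomspace(0.5, 2.5, 17)
    scans = thermo.specific_heat_scan(
        model, T_grid, cond["subset_sizes"], cond["n_subsets"], seed=s_scan,
        n_stat_bins=cond["n_stat_bins"], fit_tol=1e-4,
        mc_thermo_config=dict(n_samples=20000))
    return {"sizes": [s.n_neurons for s in scans],
            "T_peaks": [s.T_peak for s in scans],
            "peak_specific_heat": [float(s.specific_heat.max())
                                   for s in scans],
            "scans": scans}


def mc_recovery_experiment(seed: int = 0, n_neurons: int = 10,
                           n_train: int = 100000) -> dict:
    """Boltzmann-learning parameter recovery on a planted frustrated model.

    Samples ``n_train`` bins from a known (h, J), fits by Monte-Carlo moment
    matching, and reports the Pearson correlation between fitted and planted
    couplings (plus the exact-fit reference on the same data).
    """
    from .raster import empirical_stats

    ss = np.random.SeedSequence(seed)
    s_model, s_data, s_fit = [int(c.generate_state(1)[0] & 0x7FFFFFFF)
                              for c in ss.spawn(3)]
    truth = synth.make_frustrated_model(n_neurons, 0.6, -2.0, seed=s_model)
    raster = synth.sample_ising(truth, n_train, seed=s_data)
    stats = empirical_stats(raster)
    iu = np.triu_indices(n_neurons, 1)
    mc = maxent.mc_fit(stats, seed=s_fit, raise_on_fail=False)
    out = {"truth": truth, "stats": stats, "mc_model": mc,
           "r_mc": float(np.corrcoef(mc.J[iu], truth.J[iu])[0, 1])}
    if n_neurons <= maxent.EXACT_N_MAX:
        ex = maxent.exact_fit(stats)
        out["exact_model"] = ex
        out["r_exact"] = float(np.corrcoef(ex.J[iu], truth.J[iu])[0, 1])
    return out
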