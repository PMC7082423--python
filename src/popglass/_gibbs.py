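"""Numba kernels for Gibbs sampling of pairwise binary models.

Single-site heat-bath updates in a fixed sweep order (site 0..N-1), which
keeps runs bit-reproducible for a given seed.  The model convention is
``E(r) = -sum_i h_i r_i - sum_{i<j} J_ij r_i r_j`` with r in {0,1} and
``P(r) \\propto exp(-E/T)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(h, J, T, s):
    n = h.shape[0]
    for i in range(n):
        f = h[i]
        for j in range(n):
            f += J[i, j] * s[j]
        p1 = 1.0 / (1.0 + np.exp(-f / T))
        s[i] = 1.0 if np.random.random() < p1 else 0.0


@njit(cache=True)
def gibbs_sample(h, J, T, n_samples, burn_in, thin, seed):
    """Draw ``n_samples`` states after ``burn_in`` sweeps, ``thin`` sweeps apart."""
    np.random.seed(seed)
    n = h.shape[0]
    s = np.zeros(n, dtype=np.float64)
    for _ in range(burn_in):
        _sweep(h, J, T, s)
    out = np.empty((n_samples, n), dtype=np.uint8)
    for k in range(n_samples):
        for _ in range(thin):
            _sweep(h, J, T, s)
        for i in range(n):
            out[k, i] = np.uint8(s[i])
    return out


@njit(cache=True)
def gibbs_sample_resume(h, J, T, n_samples, thin, seed, state):
    """Continue a chain from ``state`` (modified in place)."""
    np.random.seed(seed)
    n = h.shape[0]
    out = np.empty((n_samples, n), dtype=np.uint8)
    for k in range(n_samples):
        for _ in range(thin):
            _sweep(h, J, T, state)
        for i in range(n):
            out[k, i] = np.uint8(state[i])
    return out


@njit(cache=True)
def ais_log_z(h, J, T, n_betas, n_chains, seed):
    """Annealed importance sampling estimate of log Z(T).

    Anneals the couplings from the independent base (J=0, same h) to the full
    model; the base log Z is closed-form.  Returns per-chain log-weights; the
    caller combines them into an estimate and a standard error.
    """
    np.random.seed(seed)
    n = h.shape[0]
    logw = np.zeros(n_chains)
    for c in range(n_chains):
        s = np.zeros(n, dtype=np.float64)
        for i in range(n):  # exact draw from the base
            p1 = 1.0 / (1.0 + np.exp(-h[i] / T))
            s[i] = 1.0 if np.random.random() < p1 else 0.0
        acc = 0.0
        for k in range(1, n_betas + 1):
            b0 = (k - 1) / n_betas
            b1 = k / n_betas
            ej = 0.0  # interaction energy of current state
            for i in range(n):
                for j in range(i + 1, n):
                    ej -= J[i, j] * s[i] * s[j]
            acc += -(b1 - b0) * ej / T
            _sweep(h, b1 * J, T, s)
        logw[c] = acc
    return logw
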