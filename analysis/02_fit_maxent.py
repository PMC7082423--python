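#!/usr/bin/env python
"""Fit pairwise maximum-entropy models to the simulated rasters.

Fits a 15-neuron subset exactly (full enumeration) and the full 40-neuron
population by Boltzmann learning, then checks parameter recovery against the
planted couplings.  Writes the fitted models and a recovery summary.
"""

import json
from pathlib import Path

import numpy as np

import popglass as pg
from popglass import maxent

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "maxent"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 17

truth = maxent.MaxEntModel.from_hdf5(DATA / "ising_model.h5")
raster = pg.BinaryRaster.from_hdf5(DATA / "ising_raster.h5")

sub_idx = np.arange(15)
sub_stats = pg.empirical_stats(raster.subset(sub_idx))
exact = maxent.exact_fit(sub_stats, tol=1e-6)
exact.to_hdf5(OUT / "exact_model_n15.h5")
iu15 = np.triu_indices(15, 1)
r15 = np.corrcoef(exact.J[iu15], truth.J[np.ix_(sub_idx, sub_idx)][iu15])[0, 1]
print(f"exact fit (N=15): moment residual "
      f"{exact.diagnostics['residual']:.2e}, "
      f"coupling recovery r = {r15:.3f} vs planted")

stats = pg.empirical_stats(raster)
mc = maxent.mc_fit(stats, dict(init="pair"), seed=SEED, raise_on_fail=False)
mc.to_hdf5(OUT / "mc_model_n40.h5")
iu = np.triu_indices(40, 1)
r40 = np.corrcoef(mc.J[iu], truth.J[iu])[0, 1]
print(f"Boltzmann learning (N=40): converged={mc.diagnostics['converged']}, "
      f"max rate residual {mc.diagnostics['residual_rates']:.4f}, "
      f"coupling recovery r = {r40:.3f}")

summary = {"exact_residual": exact.diagnostics["residual"],
           "exact_J_recovery_r": float(r15),
           "mc_converged": mc.diagnostics["converged"],
           "mc_J_recovery_r": float(r40)}
(OUT / "recovery.json").write_text(json.dumps(summary, indent=1))
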