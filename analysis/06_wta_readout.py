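#!/usr/bin/env python
"""Unsupervised cluster learning with the winner-take-all readout.

Trains a WTA layer (Hebbian feedforward plasticity, global inhibition,
homeostatic thresholds) on the planted-mode raster with two readouts per
planted cluster, then reports cluster tuning, coverage, label recovery and
the learning curve; finally verifies the ideal active-set/silent-set readout
built from the traced ridgelines.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import popglass as pg
from popglass import ridges, synth, wta

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "wta"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 57

truth = synth.ModeGroundTruth.from_json(DATA / "mode_truth.json")
raster = pg.BinaryRaster.from_hdf5(DATA / "mode_raster.h5")
labels = np.loadtxt(DATA / "mode_labels.csv", dtype=int)

n_readouts = 2 * truth.n_modes
circuit, traj = wta.train(raster, n_readouts, seed=SEED)
circuit.to_hdf5(OUT / "circuit.h5")
report = wta.evaluate(circuit, raster, labels)
curve = wta.learning_curve(traj["mean_abs_dw"], raster.n_bins // 10)
pd.DataFrame(report.tuning).to_csv(OUT / "tuning.csv")
print(f"WTA with {n_readouts} readouts over {truth.n_modes} planted "
      f"clusters: coverage {report.coverage:.2f}, "
      f"label recovery {report.accuracy:.3f}")
print(f"learning curve |dW| per block: first {curve[0]:.4f} -> "
      f"last {curve[-1]:.4f}")

# ideal readout from ridgelines traced on this raster's fitted landscape
import popglass.maxent as maxent

model = maxent.mc_fit(pg.empirical_stats(raster), dict(init="pair"),
                      seed=SEED + 1, raise_on_fail=False)
rng = np.random.default_rng(SEED + 2)
rls = {}
for t in rng.choice(raster.n_bins, 40, replace=False):
    start = raster.values[:, t].astype(np.uint8)
    if start.sum() < 2:
        continue
    sm = ridges.ascend_fixed_K(model, start, 8, int(rng.integers(1 << 31)))
    for r in ridges.trace_ridgeline(model, sm, K_limit=10,
                                    seed=int(rng.integers(1 << 31)),
                                    n_paths=8):
        rls.setdefault(tuple(r.active_set), r)
ideal = wta.ideal_circuit(list(rls.values()))
ideal_report = wta.evaluate(ideal, raster, labels)
print(f"ideal ridgeline readout ({len(rls)} units): "
      f"coverage {ideal_report.coverage:.2f}")

(OUT / "summary.json").write_text(json.dumps(
    {"coverage": report.coverage, "accuracy": report.accuracy,
     "learning_curve": curve.tolist(),
     "ideal_coverage": ideal_report.coverage}, indent=1))
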