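#!/usr/bin/env python
"""Geometry of the fitted probability landscape of the planted-mode raster.

Fits a pairwise model to the latent-mode raster, ascends from observed
patterns to soft local maxima at fixed spike count, traces ridgelines across
K, extracts active/silent sets and the K range, and matches each ridge to a
tree-HMM cluster.
"""

import json
from pathlib import Path

import numpy as np

import popglass as pg
from popglass import maxent, ridges, treehmm

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "ridges"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 47

raster = pg.BinaryRaster.from_hdf5(DATA / "mode_raster.h5")
stats = pg.empirical_stats(raster)
model = maxent.mc_fit(stats, dict(init="pair"), seed=SEED,
                      raise_on_fail=False)
print(f"pairwise model of the mode raster: converged="
      f"{model.diagnostics['converged']}")

hmm = treehmm.TreeHMM.from_hdf5(ROOT / "hmm" / "tree_hmm.h5")
rng = np.random.default_rng(SEED + 1)
k_limit = int(raster.spike_counts().max())
found = {}
ridgelines = []
for t in rng.choice(raster.n_bins, 60, replace=False):
    start = raster.values[:, t].astype(np.uint8)
    if start.sum() < 2:
        continue
    sm = ridges.ascend_fixed_K(model, start, n_paths=8,
                               seed=int(rng.integers(1 << 31)))
    key = tuple(sm.pattern)
    if key in found:
        continue
    found[key] = True
    ridgelines.extend(ridges.trace_ridgeline(
        model, sm, K_limit=min(k_limit, 12),
        seed=int(rng.integers(1 << 31)), n_paths=8))

# deduplicate by active set
uniq = {}
for r in ridgelines:
    uniq.setdefault(tuple(r.active_set), r)
ridgelines = list(uniq.values())
match = ridges.match_ridges_to_hmm(ridgelines, hmm)
ridges.save_ridgelines(ridgelines, OUT / "ridgelines.json")

print(f"{len(ridgelines)} distinct ridgelines:")
for r, m in zip(ridgelines, match):
    print(f"  K {r.K_min:2d}..{r.K_max:2d}, |active| {r.active_set.size:2d}, "
          f"HMM mode {m['matched_mode']} (purity {m['purity']:.2f})")

(OUT / "summary.json").write_text(json.dumps(
    {"n_ridgelines": len(ridgelines),
     "matches": match,
     "K_ranges": [[r.K_min, r.K_max] for r in ridgelines],
     "active_sizes": [int(r.active_set.size) for r in ridgelines]},
    indent=1))
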