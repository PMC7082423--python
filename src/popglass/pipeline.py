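"""End-to-end orchestration: simulate -> stats -> maxent -> thermo -> hmm ->
ridges -> wta -> report, driven by a single YAML-serializable config.

Each stage consumes only artifacts written by its declared upstream stages
and draws its randomness from a named child of the master seed, so a re-run
with the same config reproduces byte-identical primary artifacts.  The
``analysis/`` scripts are thin drivers over these stage functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import maxent, ridges, synth, thermo, treehmm, wta
from .raster import BinaryRaster, empirical_stats

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "stats", "maxent", "thermo", "hmm", "ridges",
               "wta", "report"]
STAGE_DEPS = {"simulate": [], "stats": ["simulate"], "maxent": ["stats"],
              "thermo": ["maxent"], "hmm": ["simulate"],
              "ridges": ["maxent", "hmm"], "wta": ["simulate", "hmm"],
              "report": []}


@dataclass
class PipelineConfig:
    """All stage toggles and parameters plus the master seed."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    simulate: dict = field(default_factory=lambda: dict(
        n_neurons=15, n_modes=3, active_size=4, p_in=0.5, p_out=0.02,
        self_transition=0.75, n_bins=4000, bin_width=0.020))
    maxent_cfg: dict = field(default_factory=lambda: dict(tol=1e-5))
    thermo_cfg: dict = field(default_factory=lambda: dict(
        T_min=0.3, T_max=3.0, n_T=25, gamma_points=6))
    hmm_cfg: dict = field(default_factory=lambda: dict(
        M=None, M_grid=[2, 3, 4], n_restarts=2, max_iters=60))
    ridges_cfg: dict = field(default_factory=lambda: dict(
        n_starts=8, n_paths=6))
    wta_cfg: dict = field(default_factory=lambda: dict(redundancy=2))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Disabling a stage disables its dependents (logged); a stage failure
    halts downstream stages and the partial manifest is still written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = dict(config.stages)
    for s in STAGE_ORDER:
        if enabled.get(s, False):
            for d in STAGE_DEPS[s]:
                if not enabled.get(d, False):
                    logger.warning("stage %s disabled: dependency %s is off",
                                   s, d)
                    enabled[s] = False
                    break
    manifest: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}
    failed = False
    for name in STAGE_ORDER:
        if not enabled.get(name, False):
            continue
        if failed:
            manifest["stages"][name] = {"status": "skipped (upstream failure)"}
            continue
        t0 = time.perf_counter()
        try:
            artifacts = _STAGE_FNS[name](config, out, state,
                                         _stage_seed(config.seed, name))
            manifest["stages"][name] = {
                "status": "ok", "seed": _stage_seed(config.seed, name),
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "artifacts": {str(p.relative_to(out)): _sha256(p)
                              for p in artifacts}}
        except Exception as err:  # halt downstream, keep partial manifest
            logger.error("stage %s failed: %s", name, err)
            manifest["stages"][name] = {"status": f"failed: {err}"}
            failed = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# -- stage implementations --------------------------------------------------

def _stage_simulate(cfg, out, state, seed):
    p = cfg.simulate
    truth = synth.make_planted_modes(
        p["n_neurons"], p["n_modes"], p["active_size"], p["p_in"], p["p_out"],
        p["self_transition"], seed=seed)
    raster, labels = synth.sample_mode_raster(truth, p["n_bins"], seed=seed,
                                              bin_width=p["bin_width"])
    state["truth"], state["raster"], state["labels"] = truth, raster, labels
    a = out / "raster.h5"
    raster.to_hdf5(a)
    b = out / "truth.json"
    truth.to_json(b)
    c = out / "labels.csv"
    np.savetxt(c, labels, fmt="%d")
    return [a, b, c]


def _stage_stats(cfg, out, state, seed):
    stats = empirical_stats(state["raster"])
    state["stats"] = stats
    prefix = out / "stats"
    stats.save(prefix)
    return [prefix.with_suffix(".m.csv"), prefix.with_suffix(".cov.csv"),
            prefix.with_suffix(".json")]


def _stage_maxent(cfg, out, state, seed):
    stats = state["stats"]
    try:
        model = maxent.fit(stats, seed=seed, **cfg.maxent_cfg)
    except ValueError as err:
        if "boundary" not in str(err) and "infeasible" not in str(err):
            raise
        # sparse data: pairs that never co-fire sit on the Frechet boundary
        # (maximum-likelihood J diverges); shrink covariances slightly
        logger.warning("boundary moments (%s); refitting with C_ij -> 0.99 "
                       "C_ij", err)
        stats = maxent.scale_correlations(stats, 0.99)
        model = maxent.fit(stats, seed=seed, **cfg.maxent_cfg)
    state["stats"] = stats
    state["maxent"] = model
    a = out / "maxent_model.h5"
    model.to_hdf5(a)
    b = out / "maxent_report.json"
    b.write_text(json.dumps(
        {"method": model.diagnostics.get("method"),
         "residual": float(model.diagnostics.get("residual", np.nan)),
         "n_neurons": model.n_neurons}, indent=1))
    return [a, b]


def _stage_thermo(cfg, out, state, seed):
    t = cfg.thermo_cfg
    grid = np.geomspace(t["T_min"], t["T_max"], t["n_T"])
    scan = thermo.scan_model(state["maxent"], grid, seed=seed)
    a = out / "thermo_scan.csv"
    np.savetxt(a, np.column_stack([scan.T_grid, scan.C, scan.specific_heat,
                                   scan.se]),
               header="T,C,C_per_N,se", delimiter=",", comments="")
    gscan = thermo.gamma_transition(
        state["stats"], np.linspace(0, 1, t["gamma_points"]), seed=seed)
    b = out / "thermo_summary.json"
    b.write_text(json.dumps(
        {"T_peak": scan.T_peak, "gamma_star": None if gscan.degenerate
         else gscan.gamma_star, "gamma_degenerate": gscan.degenerate,
         "C_at_T1_per_gamma": gscan.C_at_T1.tolist()}, indent=1))
    state["thermo"], state["gamma"] = scan, gscan
    return [a, b]


def _stage_hmm(cfg, out, state, seed):
    h = cfg.hmm_cfg
    em = dict(n_restarts=h.get("n_restarts", 2),
              max_iters=h.get("max_iters", 60))
    if h.get("M"):
        M = int(h["M"])
        table = None
    else:
        M, table = treehmm.select_num_modes(
            state["raster"], h["M_grid"], dict(em_config=em), seed=seed)
    model = treehmm.fit(state["raster"], M, em, seed=seed)
    labels = treehmm.assign(model, state["raster"])
    state["hmm"], state["hmm_labels"] = model, labels
    a = out / "hmm_model.h5"
    model.to_hdf5(a)
    b = out / "hmm_labels.csv"
    labels.to_csv(b)
    c = out / "hmm_summary.json"
    sep = treehmm.separation(state["raster"], labels.labels)
    state["separation"] = sep
    c.write_text(json.dumps(
        {"M": M, "min_dprime": sep.min_dprime,
         "cv_table": None if table is None else table.to_dict("records")},
        indent=1))
    return [a, b, c]


def _stage_ridges(cfg, out, state, seed):
    r = cfg.ridges_cfg
    model = state["maxent"]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    raster = state["raster"]
    found: dict[tuple, ridges.SoftLocalMax] = {}
    starts = rng.choice(raster.n_bins, min(r["n_starts"], raster.n_bins),
                        replace=False)
    ridgelines = []
    for t in starts:
        start = raster.values[:, t].astype(np.uint8)
        if start.sum() == 0:
            continue
        sm = ridges.ascend_fixed_K(model, start, r["n_paths"],
                                   int(rng.integers(1 << 31)))
        key = tuple(sm.pattern)
        if key in found:
            continue
        found[key] = sm
        ridgelines.extend(ridges.trace_ridgeline(
            model, sm, K_limit=int(raster.spike_counts().max()),
            seed=int(rng.integers(1 << 31)), n_paths=r["n_paths"]))
    if "hmm" in state:
        ridges.match_ridges_to_hmm(ridgelines, state["hmm"])
    state["ridgelines"] = ridgelines
    a = out / "ridgelines.json"
    ridges.save_ridgelines(ridgelines, a)
    return [a]


def _stage_wta(cfg, out, state, seed):
    m = state["truth"].n_modes
    n_readouts = cfg.wta_cfg.get("redundancy", 2) * m
    circuit, traj = wta.train(state["raster"], n_readouts, seed=seed)
    report = wta.evaluate(circuit, state["raster"], state["labels"])
    state["wta_report"] = report
    a = out / "wta_circuit.h5"
    circuit.to_hdf5(a)
    b = out / "wta_report.json"
    b.write_text(json.dumps(
        {"coverage": report.coverage, "accuracy": report.accuracy,
         "tuning": report.tuning.tolist(),
         "learning_curve": wta.learning_curve(
             traj["mean_abs_dw"], max(1, len(traj["mean_abs_dw"]) // 10)
         ).tolist()}, indent=1))
    return [a, b]


def _stage_report(cfg, out, state, seed):
    a = out / "report.md"
    a.write_text(report_text(state))
    return [a]


_STAGE_FNS = {"simulate": _stage_simulate, "stats": _stage_stats,
              "maxent": _stage_maxent, "thermo": _stage_thermo,
              "hmm": _stage_hmm, "ridges": _stage_ridges, "wta": _stage_wta,
              "report": _stage_report}


def report_text(state: dict) -> str:
    """Human-readable summary of whichever stages ran."""
    lines = ["# Pipeline report", ""]
    if "thermo" in state:
        lines += ["## Thermodynamics",
                  f"- specific-heat peak T* = {state['thermo'].T_peak:.3f}"]
        g = state.get("gamma")
        if g is not None and not g.degenerate:
            lines += [f"- correlation-scaling midpoint gamma* = "
                      f"{g.gamma_star:.3f}"]
        lines += [""]
    if "hmm" in state:
        lines += ["## Latent modes",
                  f"- M = {state['hmm'].n_modes} modes"]
        if "separation" in state:
            lines += [f"- min pairwise d' = "
                      f"{state['separation'].min_dprime:.2f}"]
        lines += [""]
    if "ridgelines" in state:
        lines += ["## Ridge geometry"]
        for k, r in enumerate(state["ridgelines"]):
            lines += [f"- ridge {k}: K {r.K_min}..{r.K_max}, "
                      f"|active set| = {r.active_set.size}, "
                      f"mode {r.matched_mode}"]
        lines += [""]
    if "wta_report" in state:
        rep = state["wta_report"]
        lines += ["## WTA readout",
                  f"- coverage = {rep.coverage:.2f}",
                  f"- label recovery = {rep.accuracy:.3f}", ""]
    return "\n".join(lines)


def report(manifest: dict) -> str:
    """Render a manifest into a short status summary."""
    lines = ["# Run manifest", f"seed: {manifest.get('seed')}", ""]
    for name, info in manifest.get("stages", {}).items():
        lines.append(f"- {name}: {info.get('status')}"
                     + (f" ({len(info.get('artifacts', {}))} artifacts, "
                        f"{info.get('wall_time_s', 0)} s)"
                        if info.get("status") == "ok" else ""))
    return "\n".join(lines)
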