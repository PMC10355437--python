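"""End-to-end study orchestration from a single YAML config.

Stages: generate (or load) a connectome, stabilize the intact network,
run a lesion sweep, and summarize FC/dynamics/graph/excitability metrics
into CSV tables. Each run writes a manifest (config snapshot, seeds,
per-stage timings, output hashes); a completed stage whose config hash is
unchanged is skipped on re-run, so studies are resumable per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import load_connectome, node_strength, save_connectome
from .excitability import delta_cei, lesion_correlations, sweep_average_map
from .hemodynamics import HemoConfig
from .homeostasis import HomeostasisConfig
from .lesion import sweep_lesions
from .metrics_dynamics import (criticality_k, detect_avalanches,
                               kuramoto_series, synchrony_metastability)
from .metrics_fc import fc_distance, fc_sc_correlation, static_fc
from .metrics_graph import consensus_modules, lesion_graph_metrics
from .neural_mass import ModelConfig
from .synth import SynthConnectomeSpec, make_connectome

__all__ = ["run_study", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "out_dir": "study_out",
    "seed": 1,
    "connectome": {"kind": "synthetic", "n_regions": 16, "density": 0.4,
                   "decay_length": 40.0, "homotopic_boost": 2.0},
    "model": {"C": 4.07, "rho": 0.2, "mean_delay": 4.0},
    "lesions": {"nodes": "all", "record_minutes": 5.0},
    "homeostasis": {"max_duration_min": 100.0},
    # SW density grid is the desk-scale adaptation: small thresholded FC
    # graphs disconnect below ~50% density, so the connected range moves up
    "graph": {"k_modules": 4, "n_random": 20,
              "sw_densities": [0.5, 0.55, 0.6, 0.65, 0.7]},
}


def _cfg_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def _phase_metrics(phase, conn, lesioned, partition, seed, n_random,
                   sw_densities):
    fc = static_fc(phase.bold)
    R = kuramoto_series(phase.bold.series)
    sync, meta = synchrony_metastability(R)
    av = detect_avalanches(phase.record.rE)
    gm = lesion_graph_metrics(fc, lesioned, partition, n_random=n_random,
                              sw_densities=np.asarray(sw_densities),
                              seed=seed)
    return {
        "fc": fc,
        "synchrony": sync, "metastability": meta,
        "k": criticality_k(av) if av.n >= 2 else np.nan,
        "Q_mean": gm["Q_mean"], "SW_mean": gm["SW_mean"],
        "fc_sc": fc_sc_correlation(fc, conn, exclude=lesioned),
    }


def run_study(config_path) -> dict:
    """Execute the staged study described by a YAML config file.

    Returns the manifest dict; all artifacts are written under the config's
    ``out_dir``.
    """
    with open(config_path) as fh:
        user_cfg = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user_cfg}
    for key in ("connectome", "model", "lesions", "homeostasis", "graph"):
        cfg[key] = {**DEFAULT_CONFIG.get(key, {}), **(user_cfg.get(key) or {})}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": cfg, "stages": {}}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            pass
        manifest["config"] = cfg

    def stage_done(name, section):
        st = manifest["stages"].get(name)
        return bool(st and st.get("hash") == _cfg_hash(section)
                    and all(Path(p).exists() for p in st.get("outputs", [])))

    def mark(name, section, outputs, t0):
        manifest["stages"][name] = {
            "hash": _cfg_hash(section),
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 2),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    seed = int(cfg["seed"])

    # stage 1: connectome
    conn_dir = out / "connectome"
    sec1 = {**cfg["connectome"], "seed": seed}
    if not stage_done("connectome", sec1):
        t0 = time.time()
        c = cfg["connectome"]
        if c["kind"] == "synthetic":
            spec = SynthConnectomeSpec(
                n_regions=c["n_regions"], density=c["density"],
                decay_length=c["decay_length"],
                homotopic_boost=c["homotopic_boost"], seed=seed)
            conn = make_connectome(spec)
        else:
            conn = load_connectome(c["weights"], c["lengths"], c["regions"])
        paths = save_connectome(conn, conn_dir)
        mark("connectome", sec1, paths.values(), t0)
    conn = load_connectome(conn_dir / "weights.csv", conn_dir / "lengths.csv",
                           conn_dir / "regions.csv")

    model = ModelConfig(seed=seed, **cfg["model"])
    homeo = HomeostasisConfig(rho=model.rho, tau_homeo=model.tau_homeo,
                              **cfg["homeostasis"])
    hemo = HemoConfig()

    # stage 2: lesion sweep + metrics (the expensive stage)
    summary_path = out / "sweep_summary.csv"
    excit_path = out / "excitability_map.csv"
    sec2 = {**cfg["model"], **cfg["lesions"], **cfg["homeostasis"],
            **cfg["graph"], "seed": seed}
    if not stage_done("sweep", sec2):
        t0 = time.time()
        nodes = cfg["lesions"]["nodes"]
        if nodes == "all":
            nodes = list(range(conn.n_regions))
        g = cfg["graph"]
        from .lesion import _record_phase, derive_seed, run_baseline
        base = run_baseline(model, conn, homeo=homeo, seed=seed)
        # module partition from an independent intact-network recording,
        # so modularity at T0/T1/T2 is scored out-of-sample
        part_phase = _record_phase(model, conn, base["cei"],
                                   cfg["lesions"]["record_minutes"] * 60.0,
                                   hemo, derive_seed(seed, -2, 0))
        part = consensus_modules(static_fc(part_phase.bold),
                                 k=g["k_modules"], runs=50, seed=seed)
        exps = sweep_lesions(cfg=model, conn=conn, nodes=nodes,
                             baseline_cei=base["cei"],
                             record_minutes=cfg["lesions"]["record_minutes"],
                             homeo=homeo, hemo=hemo, master_seed=seed)
        rows, maps = [], []
        for exp in exps:
            mets = {}
            for name in ("T0", "T1", "T2"):
                mets[name] = _phase_metrics(
                    exp.phases[name], conn, exp.lesioned_node, part, seed,
                    g["n_random"], g["sw_densities"])
            m = delta_cei(exp)
            maps.append(m)
            rows.append({
                "node": exp.lesioned_node,
                "label": conn.regions.labels[exp.lesioned_node],
                "strength": node_strength(conn)[exp.lesioned_node],
                "fc_dist_T1": fc_distance(mets["T1"]["fc"], mets["T0"]["fc"],
                                          exclude=exp.lesioned_node),
                "fc_dist_T2": fc_distance(mets["T2"]["fc"], mets["T0"]["fc"],
                                          exclude=exp.lesioned_node),
                "Q_T0": mets["T0"]["Q_mean"], "Q_T1": mets["T1"]["Q_mean"],
                "Q_T2": mets["T2"]["Q_mean"],
                "SW_T0": mets["T0"]["SW_mean"], "SW_T1": mets["T1"]["SW_mean"],
                "SW_T2": mets["T2"]["SW_mean"],
                "sync_T0": mets["T0"]["synchrony"],
                "sync_T1": mets["T1"]["synchrony"],
                "sync_T2": mets["T2"]["synchrony"],
                "meta_T0": mets["T0"]["metastability"],
                "meta_T1": mets["T1"]["metastability"],
                "meta_T2": mets["T2"]["metastability"],
                "k_T0": mets["T0"]["k"], "k_T1": mets["T1"]["k"],
                "k_T2": mets["T2"]["k"],
                "fcsc_T0": mets["T0"]["fc_sc"], "fcsc_T1": mets["T1"]["fc_sc"],
                "fcsc_T2": mets["T2"]["fc_sc"],
                "mean_delta_cei_pct": float(np.nanmean(m.delta_cei_pct)),
                "convergence_time_s": exp.convergence_time_s,
                "converged": exp.converged,
            })
        pd.DataFrame(rows).to_csv(summary_path, index=False)
        per_lesion = pd.DataFrame(
            np.vstack([m.delta_cei_pct for m in maps]),
            index=pd.Index([m.lesioned_node for m in maps], name="lesion"),
            columns=conn.regions.labels)
        per_lesion.to_csv(out / "delta_cei_per_lesion.csv")
        avg = sweep_average_map(maps, conn.regions)
        pd.DataFrame({
            "label": conn.regions.labels,
            "mean_delta_cei_pct": avg["mean"],
            "sd": avg["sd"], "sem": avg["sem"],
        }).to_csv(excit_path, index=False)
        if len(exps) >= 3:
            corr = lesion_correlations(exps, conn)
            (out / "lesion_correlations.json").write_text(
                json.dumps(corr, indent=2))
        mark("sweep", sec2, [summary_path, excit_path], t0)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
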