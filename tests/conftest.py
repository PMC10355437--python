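"""Shared fixtures: small synthetic connectomes and the lesion-sweep study.

The lesion sweep (5 lesions x 3 seeds on a 16-node connectome, 5-minute
recordings) is the desk-scale version of the whole-network stroke study;
it is expensive, so it is computed once per session and shared by every
test that interrogates its directions.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokewc import (HomeostasisConfig, ModelConfig, SynthConnectomeSpec,
                      delta_cei, fc_distance, lesion_graph_metrics,
                      make_connectome, node_strength, run_baseline,
                      run_protocol, static_fc)
from strokewc.hemodynamics import HemoConfig
from strokewc.lesion import _record_phase, derive_seed
from strokewc.metrics_graph import consensus_modules

SWEEP_SEEDS = (11, 12, 13)
N_LESIONS = 5
RECORD_MINUTES = 5.0
K_MODULES = 4  # ~4 regions per module on the 16-node fixture


@pytest.fixture(scope="session")
def small_conn():
    return make_connectome(SynthConnectomeSpec(n_regions=16, seed=7))


@pytest.fixture(scope="session")
def tiny_conn():
    return make_connectome(SynthConnectomeSpec(n_regions=8, seed=0))


@pytest.fixture()
def model_cfg():
    return ModelConfig(seed=3)


def _sweep_nodes(conn) -> list[int]:
    """Five lesion targets spanning the node-strength range."""
    order = np.argsort(node_strength(conn))
    return [int(order[i]) for i in (15, 12, 9, 6, 3)]


def _experiment_summary(exp, conn, partition):
    fcs = {k: static_fc(p.bold) for k, p in exp.phases.items()}
    node = exp.lesioned_node
    q_mean = {}
    for k, fc in fcs.items():
        gm = lesion_graph_metrics(fc, node, partition, n_random=20,
                                  seed=exp.seed)
        q_mean[k] = gm["Q_mean"]
    m = delta_cei(exp)
    return {
        "node": node,
        "seed": exp.seed,
        "strength": float(node_strength(conn)[node]),
        "fc_dist_T1": fc_distance(fcs["T1"], fcs["T0"], exclude=node),
        "fc_dist_T2": fc_distance(fcs["T2"], fcs["T0"], exclude=node),
        "Q_T0": q_mean["T0"], "Q_T1": q_mean["T1"], "Q_T2": q_mean["T2"],
        "delta_cei_pct": m.delta_cei_pct,
        "mean_delta_cei_pct": float(np.nanmean(m.delta_cei_pct)),
        "convergence_time_s": exp.convergence_time_s,
        "converged": exp.converged,
    }


@pytest.fixture(scope="session")
def lesion_sweep(small_conn):
    """5 lesions x 3 seeds with per-experiment summaries.

    Returns (experiments, summaries, conn); summaries are per-run dicts of
    FC distances, across-threshold modularity, excitability change and
    convergence time.
    """
    conn = small_conn
    nodes = _sweep_nodes(conn)
    homeo = HomeostasisConfig(rho=0.2, max_duration_min=120.0)
    experiments, summaries = [], []
    for seed in SWEEP_SEEDS:
        cfg = ModelConfig(seed=seed)
        base = run_baseline(cfg, conn, homeo=homeo, seed=seed)
        # partition from an independent intact recording: modularity at
        # T0/T1/T2 is then scored out-of-sample (the analog of deriving
        # modules from independent reference data)
        part_phase = _record_phase(cfg, conn, base["cei"],
                                   RECORD_MINUTES * 60.0, HemoConfig(),
                                   derive_seed(seed, -2, 0))
        part = consensus_modules(static_fc(part_phase.bold), k=K_MODULES,
                                 runs=50, seed=seed)
        t0_phase = None
        for node in nodes:
            exp = run_protocol(cfg, conn, node, base["cei"],
                               record_minutes=RECORD_MINUTES, homeo=homeo,
                               master_seed=seed, t0_phase=t0_phase)
            t0_phase = exp.phases["T0"]
            experiments.append(exp)
        for exp in experiments[-len(nodes):]:
            summaries.append(_experiment_summary(exp, conn, part))
    return experiments, summaries, conn
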