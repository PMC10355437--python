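"""The three-phase stroke-lesion protocol and whole-network sweeps.

A gray-matter lesion removes every connection to and from one region. The
protocol records three conditions, all with plasticity disabled during
recording: T0, the pre-lesion baseline run from converged inhibitory
weights; T1, the acute period immediately after the lesion, before any
homeostatic compensation; and T2, the chronic period after inhibitory
synaptic scaling has re-converged to a new steady state (or a maximum
adaptation duration has elapsed). The lesioned node stays in the
simulation -- isolated and noise-driven -- and is excluded from graph
metrics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, RegionSet
from .hemodynamics import BoldRecord, HemoConfig, bandpass, bold_transform
from .homeostasis import HomeostasisConfig, stabilize
from .neural_mass import ModelConfig, NetworkState, SimulationRecord, simulate

__all__ = [
    "LesionExperiment",
    "apply_lesion",
    "run_baseline",
    "run_protocol",
    "sweep_lesions",
    "mirror_to_ipsilesional",
    "derive_seed",
]

log = logging.getLogger(__name__)


@dataclass
class Phase:
    """One recorded condition: rate record plus filtered BOLD."""

    record: SimulationRecord
    bold: BoldRecord


@dataclass
class LesionExperiment:
    lesioned_node: int
    phases: dict  # {"T0": Phase, "T1": Phase, "T2": Phase}
    cei_T0: np.ndarray
    cei_T2: np.ndarray
    convergence_time_s: float
    converged: bool
    seed: int = 0


def derive_seed(master_seed: int, node: int, stage: int) -> int:
    """Deterministic per-(lesion, stage) seed below 2**31."""
    return (master_seed * 1_000_003 + node * 8191 + stage * 131) % (2 ** 31)


def apply_lesion(conn: Connectome, node: int) -> Connectome:
    """Zero row and column ``node`` of W; lengths untouched; input unchanged."""
    if not 0 <= node < conn.n_regions:
        raise IndexError(f"node {node} out of range for {conn.n_regions} regions")
    W = conn.W.copy()
    W[node, :] = 0.0
    W[:, node] = 0.0
    return Connectome(W, conn.L.copy(), conn.regions)


def _record_phase(cfg: ModelConfig, conn: Connectome, cei: np.ndarray,
                  duration_s: float, hemo: HemoConfig, seed: int) -> Phase:
    state = NetworkState.initial(conn.n_regions, cei=cei)
    rec, _ = simulate(cfg, conn, duration_s + 10.0, plasticity_on=False,
                      state=state, discard_s=10.0, seed=seed)
    bold = bandpass(bold_transform(rec, hemo), hemo)
    return Phase(record=rec, bold=bold)


def run_baseline(cfg: ModelConfig, conn: Connectome,
                 homeo: HomeostasisConfig | None = None,
                 init_cei: float = 1.0, seed: int | None = None) -> dict:
    """Stabilize the intact network (plasticity on) to get baseline weights."""
    return stabilize(cfg, conn, init_cei=init_cei, homeo=homeo, seed=seed)


def run_protocol(
    cfg: ModelConfig,
    conn: Connectome,
    node: int,
    baseline_cei: np.ndarray,
    record_minutes: float = 30.0,
    homeo: HomeostasisConfig | None = None,
    hemo: HemoConfig | None = None,
    master_seed: int | None = None,
    t0_phase: Phase | None = None,
) -> LesionExperiment:
    """Run the T0/T1/T2 protocol for one lesioned node.

    ``baseline_cei`` must be converged steady-state weights for the intact
    connectome. A pre-computed T0 phase may be passed to share the baseline
    recording across lesions of the same network and seed.
    """
    hemo = hemo or HemoConfig()
    homeo = homeo or HomeostasisConfig(rho=cfg.rho, tau_homeo=cfg.tau_homeo)
    ms = cfg.seed if master_seed is None else master_seed
    dur = record_minutes * 60.0

    if t0_phase is None:
        t0_phase = _record_phase(cfg, conn, baseline_cei, dur, hemo,
                                 derive_seed(ms, node, 0))
    lesioned = apply_lesion(conn, node)
    t1_phase = _record_phase(cfg, lesioned, baseline_cei, dur, hemo,
                             derive_seed(ms, node, 1))
    res = stabilize(cfg, lesioned, init_cei=baseline_cei, homeo=homeo,
                    seed=derive_seed(ms, node, 2))
    if not res["converged"]:
        log.warning("lesion %d: inhibitory weights did not converge within "
                    "%.0f min", node, homeo.max_duration_min)
    t2_phase = _record_phase(cfg, lesioned, res["cei"], dur, hemo,
                             derive_seed(ms, node, 3))
    return LesionExperiment(
        lesioned_node=node,
        phases={"T0": t0_phase, "T1": t1_phase, "T2": t2_phase},
        cei_T0=np.asarray(baseline_cei, dtype=float).copy(),
        cei_T2=res["cei"],
        convergence_time_s=res["time_s"],
        converged=res["converged"],
        seed=ms,
    )


def sweep_lesions(
    cfg: ModelConfig,
    conn: Connectome,
    nodes,
    baseline_cei: np.ndarray | None = None,
    record_minutes: float = 30.0,
    homeo: HomeostasisConfig | None = None,
    hemo: HemoConfig | None = None,
    master_seed: int | None = None,
    share_t0: bool = True,
) -> list[LesionExperiment]:
    """Independent protocol runs over a list of lesioned nodes.

    The baseline stabilization (and, with ``share_t0``, the T0 recording)
    is computed once per sweep; per-lesion randomness is seeded from
    (master seed, node id) so sweeps are reproducible and parallelizable.
    Per-lesion failures are isolated and logged, not fatal.
    """
    hemo = hemo or HemoConfig()
    ms = cfg.seed if master_seed is None else master_seed
    if baseline_cei is None:
        baseline_cei = run_baseline(cfg, conn, homeo=homeo, seed=ms)["cei"]
    t0_phase = None
    if share_t0:
        t0_phase = _record_phase(cfg, conn, baseline_cei,
                                 record_minutes * 60.0, hemo,
                                 derive_seed(ms, -1, 0))
    out = []
    for node in nodes:
        try:
            out.append(run_protocol(
                cfg, conn, int(node), baseline_cei,
                record_minutes=record_minutes, homeo=homeo, hemo=hemo,
                master_seed=ms, t0_phase=t0_phase,
            ))
        except Exception:
            log.exception("lesion %d failed; continuing sweep", node)
    return out


def mirror_to_ipsilesional(values: np.ndarray, lesioned_node: int,
                           regions: RegionSet) -> np.ndarray:
    """Swap homotopic values for left-hemisphere lesions.

    After mirroring, every lesion's pattern is reported with the lesioned
    hemisphere on the right, so maps can be averaged across lesions.
    Regions without a homotope keep their value in place (flagged by a
    log message). Applying the mirror twice is the identity.
    """
    values = np.asarray(values, dtype=float)
    if regions.hemisphere[lesioned_node] != "L":
        return values.copy()
    out = values.copy()
    missing = 0
    for i, j in enumerate(regions.homotope):
        if j < 0:
            missing += 1
            continue
        out[i] = values[j]
    if missing:
        log.warning("%d region(s) without homotope kept in place during "
                    "mirroring", missing)
    return out
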