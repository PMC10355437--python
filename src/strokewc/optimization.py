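"""Grid search over (coupling, target rate, mean delay) against reference FC.

For each grid point the network is stabilized (plasticity on), a recording
is taken with plasticity off, transformed to filtered BOLD, and scored
against reference FC/FCD by correlation, MSE and KS distance, alongside
synchrony, metastability and the criticality statistic. The admissible
region applies the acceptance thresholds corr >= 0.45, MSE <= 0.1,
KS <= 0.15; the working point is the admissible point with maximal
correlation, ties broken by minimal KS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome import Connectome
from .hemodynamics import HemoConfig, bandpass, bold_transform
from .homeostasis import HomeostasisConfig, stabilize
from .metrics_dynamics import (criticality_k, detect_avalanches,
                               kuramoto_series, synchrony_metastability)
from .metrics_fc import FCDMatrix, FCMatrix, fcd, fit_metrics, static_fc
from .neural_mass import ModelConfig, NetworkState, simulate

__all__ = ["GridSpec", "evaluate_point", "run_grid", "select_working_point",
           "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {"corr": 0.45, "mse": 0.1, "ks": 0.15}


@dataclass
class GridSpec:
    """Free-parameter grid; defaults span the full reference ranges."""

    C_values: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.1), np.log10(14.0), 25))
    rho_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 0.3001, 0.01), 3))
    delay_values: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 15.1, 1.0))

    def points(self):
        for c in self.C_values:
            for r in self.rho_values:
                for d in self.delay_values:
                    yield float(c), float(r), float(d)


def evaluate_point(
    cfg: ModelConfig,
    conn: Connectome,
    ref_fc: FCMatrix | None = None,
    ref_fcd: FCDMatrix | None = None,
    record_minutes: float = 30.0,
    homeo: HomeostasisConfig | None = None,
    hemo: HemoConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Stabilize, record, and score one parameter point.

    Returns the fit metrics against the references (NaN when no reference
    is given), the dynamical metrics, the converged weights and the FC/FCD
    of the recording.
    """
    hemo = hemo or HemoConfig()
    homeo = homeo or HomeostasisConfig(rho=cfg.rho, tau_homeo=cfg.tau_homeo)
    homeo = replace(homeo, rho=cfg.rho)
    base_seed = cfg.seed if seed is None else seed
    res = stabilize(cfg, conn, homeo=homeo, seed=base_seed)
    state = NetworkState.initial(conn.n_regions, cei=res["cei"])
    rec, _ = simulate(cfg, conn, record_minutes * 60.0 + 10.0,
                      plasticity_on=False, state=state, discard_s=10.0,
                      seed=base_seed + 1)
    bold = bandpass(bold_transform(rec, hemo), hemo)
    model_fc = static_fc(bold)
    model_fcd = fcd(bold)
    out = {
        "C": cfg.C, "rho": cfg.rho, "mean_delay": cfg.mean_delay,
        "seed": base_seed, "converged": res["converged"],
        "cei": res["cei"], "fc": model_fc, "fcd": model_fcd,
    }
    if ref_fc is not None:
        fm = fit_metrics(model_fc, ref_fc, model_fcd, ref_fcd)
        out.update(corr=fm.corr, mse=fm.mse, ks=fm.ks)
    else:
        out.update(corr=np.nan, mse=np.nan, ks=np.nan)
    R = kuramoto_series(bold.series)
    sync, meta = synchrony_metastability(R)
    av = detect_avalanches(rec.rE)
    out.update(synchrony=sync, metastability=meta,
               k=criticality_k(av) if av.n >= 2 else np.nan,
               n_avalanches=av.n)
    return out


def run_grid(
    base_cfg: ModelConfig,
    conn: Connectome,
    grid: GridSpec,
    ref_fc: FCMatrix,
    ref_fcd: FCDMatrix | None = None,
    record_minutes: float = 30.0,
    homeo: HomeostasisConfig | None = None,
    hemo: HemoConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Evaluate every grid point; long-format results, order-independent."""
    rows = []
    for C, rho, delay in grid.points():
        cfg = replace(base_cfg, C=C, rho=rho, mean_delay=delay)
        r = evaluate_point(cfg, conn, ref_fc, ref_fcd,
                           record_minutes=record_minutes, homeo=homeo,
                           hemo=hemo, seed=seed)
        rows.append({k: r[k] for k in
                     ("C", "rho", "mean_delay", "seed", "converged", "corr",
                      "mse", "ks", "synchrony", "metastability", "k",
                      "n_avalanches")})
    return pd.DataFrame(rows)


def select_working_point(results: pd.DataFrame,
                         thresholds: dict = DEFAULT_THRESHOLDS) -> dict:
    """Apply the acceptance thresholds and choose the working point.

    Admissible points satisfy corr >= corr_min, MSE <= mse_max and
    KS <= ks_max; the chosen point maximizes correlation with ties broken
    by minimal KS. With an empty admissible set the best-correlation point
    is returned with ``admissible=False`` (warning path).
    """
    if results.empty:
        raise ValueError("empty grid results")
    ok = (
        (results["corr"] >= thresholds["corr"])
        & (results["mse"] <= thresholds["mse"])
        & (results["ks"] <= thresholds["ks"])
    )
    pool = results[ok] if ok.any() else results
    pool = pool.sort_values(["corr", "ks"], ascending=[False, True],
                            kind="stable")
    chosen = pool.iloc[0].to_dict()
    return {"chosen": chosen, "admissible": bool(ok.any()),
            "admissible_mask": ok.to_numpy()}
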