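"""Long-term excitability changes and their spatial structure.

Excitability changes are read out as the percentage change in local
inhibitory weight between baseline and the chronic steady state,

    delta_cei_pct_i = 100 (c_EI,i(T2) - c_EI,i(T0)) / c_EI,i(T0),

with *negative* values meaning decreased inhibition, i.e. increased
excitability. Lesions remove incoming excitation, so homeostasis lowers
inhibition across the network and the sweep-mean change is negative. The
spatial pattern around a lesion is summarized by an exponential fit
against Euclidean distance to the lesioned region, by correlations with
structural weight to the lesion and with lesion strength, and by an
asymmetry index between homotopic (e.g. motor-cortex) weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .connectome import Connectome, node_strength
from .lesion import LesionExperiment, mirror_to_ipsilesional

__all__ = [
    "ExcitabilityMap",
    "delta_cei",
    "exp_distance_fit",
    "asymmetry_index",
    "lesion_correlations",
    "sweep_average_map",
]


@dataclass
class ExcitabilityMap:
    """Per-region percentage change in c_EI; the lesioned entry is NaN."""

    delta_cei_pct: np.ndarray
    lesioned_node: int
    mirrored: bool = False

    @property
    def n(self) -> int:
        return self.delta_cei_pct.size

    def valid(self) -> np.ndarray:
        return np.isfinite(self.delta_cei_pct)


def delta_cei(exp: LesionExperiment) -> ExcitabilityMap:
    """Percentage change in local inhibition from baseline to chronic."""
    c0 = np.asarray(exp.cei_T0, dtype=float)
    c2 = np.asarray(exp.cei_T2, dtype=float)
    mask = np.ones(c0.size, dtype=bool)
    mask[exp.lesioned_node] = False
    if (c0[mask] <= 0).any():
        raise ValueError("zero or negative baseline inhibitory weight")
    pct = 100.0 * (c2 - c0) / c0
    pct[exp.lesioned_node] = np.nan  # meaningless post-lesion
    return ExcitabilityMap(delta_cei_pct=pct, lesioned_node=exp.lesioned_node)


def exp_distance_fit(map_: ExcitabilityMap,
                     distances_to_lesion: np.ndarray) -> dict:
    """Least-squares fit of delta_cei = a exp(-d / lam) + c.

    Returns amplitude, length constant (mm), offset and R^2. On a
    non-convergent fit the best attempt is returned with ``converged``
    False.
    """
    d = np.asarray(distances_to_lesion, dtype=float)
    y = map_.delta_cei_pct
    ok = np.isfinite(y) & np.isfinite(d)
    ok[map_.lesioned_node] = False
    if ok.sum() < 4:
        raise ValueError("need at least 4 regions for the exponential fit")
    d, y = d[ok], y[ok]

    def model(x, a, lam, c):
        return a * np.exp(-x / lam) + c

    # Length constants far beyond the sampled distance range are not
    # identifiable (the curve degenerates to a line), so lambda is capped
    # at 3x the distance span; several starts guard against local optima.
    span = max(d.max() - d.min(), 1.0)
    lam_max = 3.0 * span
    amp0 = y[np.argmin(d)] - y.mean()
    best, converged = None, False
    for lam0 in (span / 10.0, span / 3.0, span):
        try:
            popt, _ = curve_fit(model, d, y, p0=(amp0, lam0, y.mean()),
                                bounds=([-np.inf, 1e-6, -np.inf],
                                        [np.inf, lam_max, np.inf]),
                                maxfev=10000)
        except RuntimeError:
            continue
        sse = np.sum((y - model(d, *popt)) ** 2)
        if best is None or sse < best[0]:
            best, converged = (sse, popt), True
    popt = best[1] if best is not None else (amp0, span / 3.0, y.mean())
    resid = y - model(d, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return {"amplitude": float(popt[0]), "length_mm": float(popt[1]),
            "offset": float(popt[2]), "r2": float(r2), "converged": converged}


def asymmetry_index(cei_T0: np.ndarray, cei_T2: np.ndarray,
                    left_region: int, right_region: int) -> float:
    """Change in right/left inhibitory-weight asymmetry, T0 to T2.

    index = [c_R(T2)/c_L(T2)] / [c_R(T0)/c_L(T0)] - 1; negative values
    mean excitability rose more on the right than the left.
    """
    vals = [cei_T0[left_region], cei_T0[right_region],
            cei_T2[left_region], cei_T2[right_region]]
    if any(v <= 0 for v in vals):
        raise ValueError("asymmetry index undefined for non-positive weights")
    ratio_t2 = cei_T2[right_region] / cei_T2[left_region]
    ratio_t0 = cei_T0[right_region] / cei_T0[left_region]
    return float(ratio_t2 / ratio_t0 - 1.0)


def lesion_correlations(experiments: list[LesionExperiment],
                        conn: Connectome) -> dict:
    """Correlations of excitability change with structural lesion properties.

    (i) pooled per-region delta_cei against structural weight to the
    lesioned node (over all lesions, lesioned entries excluded);
    (ii) per-lesion mean delta_cei against lesioned-node strength.
    p-values are the regression F-test (identical to the two-sided Pearson
    test for simple regression).
    """
    if len(experiments) < 3:
        raise ValueError("need at least 3 lesions")
    strengths = node_strength(conn)
    w_pool, d_pool, mean_d, lesion_s = [], [], [], []
    for exp in experiments:
        m = delta_cei(exp)
        ok = m.valid()
        w_pool.append(conn.W[exp.lesioned_node, ok])
        d_pool.append(m.delta_cei_pct[ok])
        mean_d.append(np.nanmean(m.delta_cei_pct))
        lesion_s.append(strengths[exp.lesioned_node])
    w_pool = np.concatenate(w_pool)
    d_pool = np.concatenate(d_pool)
    if np.ptp(w_pool) == 0 or np.ptp(d_pool) == 0:
        raise ValueError("degenerate variance; correlations undefined")
    r_w, p_w = stats.pearsonr(w_pool, d_pool)
    r_s, p_s = stats.pearsonr(lesion_s, mean_d)
    return {
        "r_weight": float(r_w), "p_weight": float(p_w),
        "r_strength": float(r_s), "p_strength": float(p_s),
        "n_pooled": int(d_pool.size), "n_lesions": len(experiments),
    }


def sweep_average_map(maps: list[ExcitabilityMap], regions,
                      groups: dict | None = None) -> dict:
    """Mirrored mean excitability-change map across lesions.

    Left-lesion maps are mirrored first so the lesioned hemisphere always
    lies on the same side, then averaged region-wise (NaN-aware: each
    lesion's own entry is missing). Returns per-region mean, SD and SEM,
    plus optional summaries over named region groups (lists of indices).
    """
    n = maps[0].n
    if any(m.n != n for m in maps):
        raise ValueError("inconsistent region sets across maps")
    stacked = np.vstack([
        m.delta_cei_pct if m.mirrored else
        mirror_to_ipsilesional(m.delta_cei_pct, m.lesioned_node, regions)
        for m in maps
    ])
    mean = np.nanmean(stacked, axis=0)
    sd = np.nanstd(stacked, axis=0, ddof=1)
    count = np.isfinite(stacked).sum(axis=0)
    sem = sd / np.sqrt(np.maximum(count, 1))
    out = {"mean": mean, "sd": sd, "sem": sem, "n_lesions": len(maps)}
    if groups:
        out["groups"] = {
            name: {"mean": float(np.nanmean(stacked[:, idx])),
                   "sd": float(np.nanstd(stacked[:, idx], ddof=1))}
            for name, idx in groups.items()
        }
    return out
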