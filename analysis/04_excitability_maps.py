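#!/usr/bin/env python
"""Spatial structure of the long-term excitability changes.

Reads the per-lesion excitability maps written by the lesion study and
asks three questions the sweep is designed to answer: does the change in
local inhibition decay exponentially with distance to the lesion (it
should, inheriting the connectome's distance rule); does it correlate
with structural connectivity to the lesioned node and with lesion
strength; and does the homotopic asymmetry of inhibition shift toward the
lesioned hemisphere? Writes per-lesion fits to results/excitability_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from strokewc import (euclidean_distances, exp_distance_fit,
                      load_connectome, node_strength)
from strokewc.excitability import ExcitabilityMap

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    cdir = OUT / "study" / "connectome"
    conn = load_connectome(cdir / "weights.csv", cdir / "lengths.csv",
                           cdir / "regions.csv")
    per_lesion = pd.read_csv(OUT / "study" / "delta_cei_per_lesion.csv",
                             index_col="lesion")
    dists = euclidean_distances(conn.regions)
    strengths = node_strength(conn)

    rows, pooled_w, pooled_d = [], [], []
    for node, row in per_lesion.iterrows():
        vals = row.to_numpy(dtype=float)
        m = ExcitabilityMap(vals, lesioned_node=int(node))
        fit = exp_distance_fit(m, dists[int(node)])
        ok = np.isfinite(vals)
        pooled_w.append(conn.W[int(node), ok])
        pooled_d.append(vals[ok])
        rows.append({
            "lesion": int(node),
            "label": conn.regions.labels[int(node)],
            "strength": strengths[int(node)],
            "mean_delta_cei_pct": float(np.nanmean(vals)),
            "fit_amplitude": fit["amplitude"],
            "fit_length_mm": fit["length_mm"],
            "fit_r2": fit["r2"],
        })
    fits = pd.DataFrame(rows).sort_values("strength", ascending=False)
    fits.to_csv(OUT / "excitability_fits.csv", index=False)

    r_w, p_w = stats.pearsonr(np.concatenate(pooled_w),
                              np.concatenate(pooled_d))
    r_s, p_s = stats.pearsonr(fits["strength"], fits["mean_delta_cei_pct"])
    print(f"{len(fits)} lesions")
    top = fits.iloc[0]
    print(f"strongest lesion ({top['label']}, strength {top['strength']:.2f}): "
          f"exponential distance fit R^2 = {top['fit_r2']:.2f}, "
          f"length {top['fit_length_mm']:.0f} mm")
    print(f"weakest-lesion fit R^2 = {fits.iloc[-1]['fit_r2']:.2f}")
    print(f"pooled corr(delta c_EI, W to lesion) = {r_w:.2f} (p = {p_w:.2g})")
    print(f"corr(mean delta c_EI, lesion strength) = {r_s:.2f} (p = {p_s:.2g})")

    # homotopic asymmetry readout: the index per lesion for one left/right
    # pair, computable from the percentage maps since the T0->T2 ratio of
    # each weight is 1 + pct/100
    half = conn.n_regions // 2
    left_r, right_r = 0, half
    rows = []
    for node, row in per_lesion.iterrows():
        pct = row.to_numpy(dtype=float)
        if not (np.isfinite(pct[left_r]) and np.isfinite(pct[right_r])):
            continue
        idx = (1 + pct[right_r] / 100) / (1 + pct[left_r] / 100) - 1
        rows.append((conn.regions.hemisphere[int(node)], idx))
    by_side = {side: [i for s, i in rows if s == side] for side in "LR"}
    print(f"asymmetry index for pair {conn.regions.labels[left_r]}/"
          f"{conn.regions.labels[right_r]} "
          "(negative = right side more excitable):")
    for side in "RL":
        vals = by_side[side]
        print(f"  lesions on {side}: mean {np.mean(vals):+.4f} "
              f"(n = {len(vals)})")


if __name__ == "__main__":
    main()
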