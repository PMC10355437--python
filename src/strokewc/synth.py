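"""Synthetic connectomes and reference BOLD fixtures.

The generator emulates the statistical structure the analysis assumes of
DTI connectomes: connection weight decaying exponentially with Euclidean
distance (with heavy-tailed multiplicative jitter), bilateral mirror
symmetry with boosted homotopic links, a zero diagonal, and tract lengths
equal to Euclidean distance. Reference BOLD fixtures with planted community
structure stand in for empirical resting-state data when exercising fit
metrics and consensus clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import Connectome, RegionSet, euclidean_distances

__all__ = ["SynthConnectomeSpec", "make_connectome", "make_reference_signals"]


@dataclass
class SynthConnectomeSpec:
    """Parameters of the synthetic-connectome generator.

    ``n_regions`` must be even (hemispheric mirroring). ``decay_length`` is
    the exponential length constant of the weight-distance rule in mm;
    ``homotopic_boost`` multiplies mirror-pair weights before thresholding;
    ``density`` is the fraction of node pairs kept as edges;
    ``jitter_sigma`` is the log-scale SD of the multiplicative lognormal
    weight jitter (0 disables it). Weights are rescaled after thresholding
    so the mean node strength is 1.
    """

    n_regions: int = 16
    decay_length: float = 40.0
    homotopic_boost: float = 2.0
    density: float = 0.4
    jitter_sigma: float = 0.5
    hemisphere_radius: float = 60.0
    hemisphere_gap: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even count >= 2")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")


def _mirror_coords(spec: SynthConnectomeSpec, rng: np.random.Generator):
    """Place n/2 points in a right-hemisphere ball, mirror through x=0."""
    half = spec.n_regions // 2
    cx = spec.hemisphere_gap / 2.0 + spec.hemisphere_radius / 2.0
    pts = []
    while len(pts) < half:
        p = rng.uniform(-1, 1, size=3)
        if p @ p <= 1.0:
            pts.append(p)
    right = np.array(pts) * spec.hemisphere_radius + np.array([cx, 0.0, 0.0])
    left = right * np.array([-1.0, 1.0, 1.0])
    return np.vstack([left, right])


def make_connectome(spec: SynthConnectomeSpec) -> Connectome:
    """Generate a mirror-symmetric distance-rule connectome.

    Regions ``0..n/2-1`` are the left hemisphere, ``n/2..n-1`` the right;
    region ``i`` and ``i + n/2`` are homotopic partners.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    half = n // 2
    coords = _mirror_coords(spec, rng)
    labels = [f"L{i:02d}" for i in range(half)] + [f"R{i:02d}" for i in range(half)]
    hemi = np.array(["L"] * half + ["R"] * half)
    homotope = np.concatenate([np.arange(half) + half, np.arange(half)])
    regions = RegionSet(labels, hemi, coords, homotope)

    d = euclidean_distances(regions)
    with np.errstate(over="ignore"):
        W = np.exp(-d / spec.decay_length)
    if spec.jitter_sigma > 0:
        jit = rng.lognormal(mean=0.0, sigma=spec.jitter_sigma, size=(n, n))
        jit = np.triu(jit, 1)
        W = W * (jit + jit.T)
    np.fill_diagonal(W, 0.0)
    W[np.arange(half), np.arange(half) + half] *= spec.homotopic_boost
    W[np.arange(half) + half, np.arange(half)] *= spec.homotopic_boost

    # density threshold on the upper triangle
    iu, ju = np.triu_indices(n, 1)
    vals = W[iu, ju]
    n_keep = int(round(spec.density * vals.size))
    keep = np.zeros(vals.size, dtype=bool)
    order = np.lexsort((ju, iu, -vals))  # stable: value desc, then (row, col)
    keep[order[:n_keep]] = True
    Wt = np.zeros_like(W)
    Wt[iu[keep], ju[keep]] = vals[keep]
    Wt = Wt + Wt.T

    s = Wt.sum(axis=0).mean()
    if s > 0:
        Wt /= s

    g = nx.from_numpy_array(Wt)
    if not nx.is_connected(g):
        warnings.warn(
            "synthetic connectome is disconnected at the requested density; "
            "modularity remains computable but small-world does not",
            stacklevel=2,
        )
    L = d.copy()
    return Connectome(Wt, L, regions)


def make_reference_signals(
    n_regions: int,
    n_samples: int,
    n_communities: int,
    seed: int = 0,
    tr: float = 0.72,
    within_corr: float = 0.6,
    noise_sd: float = 1.0,
):
    """Correlated Gaussian series with planted block-community covariance.

    Each region belongs to one of ``n_communities`` equal-size blocks;
    regions in the same block share a latent signal giving pairwise
    correlation ``within_corr`` within blocks and 0 between blocks. Returns
    an unfiltered :class:`~strokewc.hemodynamics.BoldRecord` at the given
    TR, plus the planted block labels.
    """
    from .hemodynamics import BoldRecord

    if n_communities > n_regions:
        raise ValueError("n_communities cannot exceed n_regions")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_regions) % n_communities
    latent = rng.standard_normal((n_communities, n_samples))
    # x = a*shared + b*noise gives corr a^2/(a^2+b^2) within blocks
    a = np.sqrt(within_corr)
    b = np.sqrt(1.0 - within_corr)
    series = a * latent[labels] + b * rng.standard_normal((n_regions, n_samples))
    series *= noise_sd
    return BoldRecord(series=series, tr=tr, filtered=False), labels
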