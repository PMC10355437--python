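"""Structural connectomes: loading, validation, and region geometry.

A connectome is a pair of symmetric non-negative matrices over the same
parcellation -- white-matter connection weights ``W`` and tract lengths ``L``
(mm) -- plus region metadata (labels, hemisphere, 3-D coordinates in mm, and
an optional homotopic mirror partner per region). All simulation and
lesioning in this package acts on this substrate.

File dialect: plain-text CSV. Matrices are headerless square CSV; the region
table has columns ``label, hemisphere, x, y, z, homotope_label`` (empty
homotope_label means no mirror partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "RegionSet",
    "Connectome",
    "load_connectome",
    "save_connectome",
    "node_strength",
    "euclidean_distances",
]


@dataclass
class RegionSet:
    """Region metadata for one parcellation.

    Parameters
    ----------
    labels
        Unique region names, length N.
    hemisphere
        Per-region 'L'/'R' flag.
    coords
        (N, 3) positions in mm.
    homotope
        Per-region index of the mirror partner in the opposite hemisphere,
        or -1 where no partner is defined.
    """

    labels: list[str]
    hemisphere: np.ndarray
    coords: np.ndarray
    homotope: np.ndarray = field(default=None)

    def __post_init__(self):
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.labels)
        if self.homotope is None:
            self.homotope = np.full(n, -1, dtype=int)
        self.homotope = np.asarray(self.homotope, dtype=int)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        n = self.n
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        if self.hemisphere.shape != (n,):
            raise ValueError("hemisphere flags must match number of labels")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise ValueError("hemisphere flags must be 'L' or 'R'")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.homotope.shape != (n,):
            raise ValueError("homotope map must have one entry per region")
        for i, j in enumerate(self.homotope):
            if j < 0:
                continue
            if j >= n:
                raise ValueError(f"homotope index {j} out of range")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(
                    f"homotope of {self.labels[i]} is in the same hemisphere"
                )
            if self.homotope[j] != i:
                raise ValueError("homotopy must be symmetric")


@dataclass
class Connectome:
    """Weights ``W``, tract lengths ``L`` (mm) and region metadata."""

    W: np.ndarray
    L: np.ndarray
    regions: RegionSet

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.regions.n

    def validate(self) -> None:
        n = self.regions.n
        for name, M in (("W", self.W), ("L", self.L)):
            if M.shape != (n, n):
                raise ValueError(f"{name} must be ({n}, {n}), got {M.shape}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.diag(M).any():
                raise ValueError(f"{name} must have a zero diagonal")
        if (self.W < 0).any():
            raise ValueError("W must be non-negative")
        mask = self.W > 0
        if not (self.L[mask] > 0).all():
            raise ValueError("L must be positive wherever W is nonzero")

    def copy(self) -> "Connectome":
        return Connectome(self.W.copy(), self.L.copy(), self.regions)


def _read_matrix(path) -> np.ndarray:
    M = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {M.shape}")
    return M


def _symmetrize(M: np.ndarray, name: str, rel_tol: float) -> np.ndarray:
    scale = np.abs(M).max()
    if scale == 0:
        return M
    asym = np.abs(M - M.T).max() / scale
    if asym > rel_tol:
        raise ValueError(
            f"{name} asymmetry {asym:.3g} exceeds tolerance {rel_tol:.3g}"
        )
    return (M + M.T) / 2.0


def load_connectome(
    weights_path,
    lengths_path,
    regions_path,
    asym_tol: float = 1e-8,
    normalize: str | None = None,
) -> Connectome:
    """Load and validate a connectome from CSV files.

    Matrices are symmetrized by averaging when the relative asymmetry is at
    most ``asym_tol`` (DTI-derived matrices are nominally symmetric), and
    self-connections are always forced to zero. ``normalize`` may be ``None``
    (weights as loaded, the default), ``"max"`` (divide by the largest
    weight) or ``"mean_strength"`` (scale so the mean node strength is 1).
    """
    W = _read_matrix(weights_path)
    L = _read_matrix(lengths_path)
    if W.shape != L.shape:
        raise ValueError(
            f"weights {W.shape} and lengths {L.shape} dimensions differ"
        )
    if (W < 0).any():
        raise ValueError("negative weights in connectivity matrix")
    W = _symmetrize(W, "weights", asym_tol)
    L = _symmetrize(L, "lengths", asym_tol)
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(L, 0.0)

    table = pd.read_csv(regions_path, dtype={"label": str, "homotope_label": str},
                        float_precision="round_trip")
    required = {"label", "hemisphere", "x", "y", "z"}
    if not required <= set(table.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    if len(table) != W.shape[0]:
        raise ValueError(
            f"region table has {len(table)} rows for a {W.shape[0]}-region matrix"
        )
    labels = table["label"].tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    homotope = np.full(len(labels), -1, dtype=int)
    if "homotope_label" in table.columns:
        for i, h in enumerate(table["homotope_label"]):
            if isinstance(h, str) and h.strip():
                if h not in index:
                    raise ValueError(f"unknown homotope label {h!r}")
                homotope[i] = index[h]
    regions = RegionSet(
        labels=labels,
        hemisphere=table["hemisphere"].to_numpy(),
        coords=table[["x", "y", "z"]].to_numpy(dtype=float),
        homotope=homotope,
    )
    if normalize == "max":
        if W.max() > 0:
            W = W / W.max()
    elif normalize == "mean_strength":
        s = W.sum(axis=0).mean()
        if s > 0:
            W = W / s
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    return Connectome(W, L, regions)


def save_connectome(conn: Connectome, out_dir) -> dict[str, Path]:
    """Write a connectome as weights.csv, lengths.csv, regions.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": out / "weights.csv",
        "lengths": out / "lengths.csv",
        "regions": out / "regions.csv",
    }
    # %.17g round-trips float64 exactly through text
    np.savetxt(paths["weights"], conn.W, delimiter=",", fmt="%.17g")
    np.savetxt(paths["lengths"], conn.L, delimiter=",", fmt="%.17g")
    r = conn.regions
    table = pd.DataFrame(
        {
            "label": r.labels,
            "hemisphere": r.hemisphere,
            "x": r.coords[:, 0],
            "y": r.coords[:, 1],
            "z": r.coords[:, 2],
            "homotope_label": [
                r.labels[j] if j >= 0 else "" for j in r.homotope
            ],
        }
    )
    table.to_csv(paths["regions"], index=False, float_format="%.17g")
    return paths


def node_strength(conn: Connectome) -> np.ndarray:
    """Sum of connection weights per region (column sums of W)."""
    return conn.W.sum(axis=0)


def euclidean_distances(regions: RegionSet) -> np.ndarray:
    """Pairwise Euclidean distance between region centroids (mm)."""
    if regions.coords is None or not np.isfinite(regions.coords).all():
        raise ValueError("region coordinates missing or non-finite")
    d = cdist(regions.coords, regions.coords)
    np.fill_diagonal(d, 0.0)
    return d
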