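"""Density thresholding, consensus modules, modularity and small-worldness.

FC matrices are turned into unweighted graphs by keeping the top fraction
(density) of strongest off-diagonal correlations. Modules are fixed a
priori: k-means is run many times on the rows of a reference FC matrix, a
co-assignment (association) matrix is accumulated, and one final k-means
on the association matrix yields the consensus partition. Modularity for a
fixed partition M is

    Q = sum_{u in M} [ e_uu - (sum_{v in M} e_uv)^2 ]

with e_uu the fraction of edges inside module u and the row sum the
fraction of edge *ends* attached to u (standard Newman accounting, so a
single all-covering module gives Q = 0). Small-worldness is

    SW = (C / C_rand) / (L / L_rand)

with C the average clustering coefficient and L the characteristic path
length, normalized by the mean over Erdos-Renyi graphs with the same node
and edge count (resampled until connected).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .metrics_fc import FCMatrix

__all__ = [
    "BinaryGraph",
    "ModulePartition",
    "threshold_graph",
    "consensus_modules",
    "modularity",
    "small_world",
    "lesion_graph_metrics",
]

Q_DENSITIES = np.arange(0.04, 0.41, 0.02)
SW_DENSITIES = np.arange(0.20, 0.41, 0.02)


@dataclass
class BinaryGraph:
    adjacency: np.ndarray
    density: float

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class ModulePartition:
    assignment: np.ndarray
    k: int
    provenance: str = ""

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n(self) -> int:
        return self.assignment.size

    def without_node(self, node: int) -> "ModulePartition":
        return ModulePartition(np.delete(self.assignment, node), self.k,
                               self.provenance)


def threshold_graph(fc: FCMatrix | np.ndarray, density: float) -> BinaryGraph:
    """Keep the top ``density`` fraction of off-diagonal values as edges.

    Ties at the cutoff are broken deterministically by a stable sort on
    (value desc, row, col).
    """
    vals_mat = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = vals_mat.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = vals_mat[iu, ju]
    n_keep = int(round(density * vals.size))
    order = np.lexsort((ju, iu, -vals))
    adj = np.zeros((n, n), dtype=int)
    sel = order[:n_keep]
    adj[iu[sel], ju[sel]] = 1
    adj = adj + adj.T
    return BinaryGraph(adjacency=adj, density=density)


def consensus_modules(fc: FCMatrix | np.ndarray, k: int = 6, runs: int = 200,
                      seed: int = 0) -> ModulePartition:
    """Consensus k-means partition of an FC matrix.

    k-means is applied ``runs`` times (different initializations) to the
    rows of the FC matrix; co-assignments are accumulated into an N x N
    association matrix, which is clustered once more with k-means to give
    the final partition. Deterministic for a given seed.
    """
    X = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot extract {k} modules from {n} regions")
    if not np.isfinite(X).all() or np.allclose(X, X[0, 0]):
        raise ValueError("degenerate FC matrix")
    assoc = np.zeros((n, n))
    for r in range(runs):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + r)
        lab = km.fit_predict(X)
        assoc += lab[:, None] == lab[None, :]
    assoc /= runs
    final = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignment = final.fit_predict(assoc)
    return ModulePartition(assignment=assignment, k=k, provenance="consensus-kmeans")


def modularity(g: BinaryGraph, p: ModulePartition) -> float:
    """Newman modularity Q of a binary graph under a fixed partition."""
    adj = g.adjacency
    if p.n != g.n:
        raise ValueError("partition size does not match graph")
    E = adj.sum() / 2.0
    if E == 0:
        raise ValueError("edgeless graph has undefined modularity")
    q = 0.0
    for u in np.unique(p.assignment):
        in_u = p.assignment == u
        e_uu = adj[np.ix_(in_u, in_u)].sum() / 2.0 / E
        a_u = adj[in_u].sum() / 2.0 / E  # fraction of edge ends in u
        q += e_uu - a_u ** 2
    return float(q)


def small_world(g: BinaryGraph, n_random: int = 100, seed: int = 0,
                max_attempts: int = 1000) -> float:
    """Small-world coefficient against same-density random graphs."""
    G = g.to_networkx()
    if g.n_edges == 0 or not nx.is_connected(G):
        raise ValueError("small-world coefficient requires a connected graph")
    C = nx.average_clustering(G)
    L = nx.average_shortest_path_length(G)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for r in range(n_random):
        for _ in range(max_attempts):
            R = nx.gnm_random_graph(g.n, g.n_edges,
                                    seed=int(rng.integers(2 ** 31)))
            if nx.is_connected(R):
                break
        else:
            raise RuntimeError("could not sample a connected random graph")
        c_rand[r] = nx.average_clustering(R)
        l_rand[r] = nx.average_shortest_path_length(R)
    cr, lr = c_rand.mean(), l_rand.mean()
    if cr == 0:
        raise ValueError("random-graph clustering is zero; SW undefined")
    return float((C / cr) / (L / lr))


def lesion_graph_metrics(
    fc: FCMatrix,
    lesioned_node: int | None,
    partition: ModulePartition,
    q_densities: np.ndarray = Q_DENSITIES,
    sw_densities: np.ndarray = SW_DENSITIES,
    n_random: int = 20,
    seed: int = 0,
) -> dict:
    """Per-density modularity and small-worldness with the lesion removed.

    The lesioned region's row/column (and partition entry) are removed
    before thresholding. Small-world values are NaN at densities where the
    thresholded graph is disconnected. Returns per-density arrays plus
    across-density means (NaN-aware for SW).
    """
    if lesioned_node is not None:
        fc = fc.without_node(lesioned_node)
        partition = partition.without_node(lesioned_node)
    Q = np.empty(len(q_densities))
    for i, d in enumerate(q_densities):
        g = threshold_graph(fc, float(d))
        Q[i] = modularity(g, partition)
    SW = np.full(len(sw_densities), np.nan)
    for i, d in enumerate(sw_densities):
        g = threshold_graph(fc, float(d))
        try:
            SW[i] = small_world(g, n_random=n_random, seed=seed + i)
        except ValueError:
            pass  # disconnected at this density
    return {
        "q_densities": np.asarray(q_densities, dtype=float),
        "Q": Q,
        "sw_densities": np.asarray(sw_densities, dtype=float),
        "SW": SW,
        "Q_mean": float(Q.mean()),
        "SW_mean": float(np.nanmean(SW)) if np.isfinite(SW).any() else float("nan"),
    }
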