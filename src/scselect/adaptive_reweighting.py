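"""Adaptive reweighting: label-free, approximately balanced cell selection.

Cluster the cells (SNN graph + modularity community detection on the first
30 PCs), then sample the same number of cells from every cluster (naive
variant) or from every marker-assigned putative cell type (marker-aware
variant).  When a pool is smaller than its quota, all its cells are taken
and the deficit is redistributed evenly over the pools with spare capacity.

The point: rare cell types typically form their own clusters, so even
per-cluster sampling yields a far more class-balanced labelled set than a
random draw — without using a single label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core_data import ExpressionDataset, MarkerSpec
from .initial_selection import SelectionResult, score_cells_by_markers

logger = logging.getLogger(__name__)

#: SNN edges with Jaccard weight below this are pruned (Seurat-family default).
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus the parameters that produced them."""

    cluster_ids: np.ndarray
    cell_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if len(self.cluster_ids) != len(self.cell_ids):
            raise ValueError("cluster assignment length mismatch")
        uniq = np.unique(self.cluster_ids)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.max()) + 1


@dataclass
class ClusterTypeMap:
    """Marker-enrichment matrix per (cluster, type) and the argmax assignment."""

    enrichment: np.ndarray   # clusters x types
    types: list[str]
    assigned_type: dict[int, str]

    def __post_init__(self) -> None:
        for c, t in self.assigned_type.items():
            j = int(np.argmax(self.enrichment[c]))
            if self.types[j] != t:
                raise ValueError("assigned_type must be the enrichment argmax")


def snn_graph(embedding: np.ndarray, n_neighbors: int = 20,
              prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighbourhood is itself plus its k nearest Euclidean
    neighbours; edge weight between two cells is the Jaccard overlap of
    their neighbourhoods, pruned below *prune*.
    """
    n = embedding.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n), dtype=float
    )
    A.data[:] = 1.0  # self may duplicate a neighbour slot
    shared = (A @ A.T).tocoo()
    k = np.asarray(A.sum(axis=1)).ravel()
    union = k[shared.row] + k[shared.col] - shared.data
    jacc = shared.data / union
    keep = (jacc >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])),
                         shape=(n, n))


def cluster_cells(embedding: np.ndarray, resolution: float = 0.8,
                  n_neighbors: int = 20, seed: int = 0,
                  cell_ids=None) -> ClusterAssignment:
    """SNN-graph modularity clustering of cells in PCA space.

    Leiden community detection with a resolution parameter on the
    Jaccard-weighted shared-nearest-neighbor graph; deterministic given the
    seed.  *embedding* should be the first 30 principal components.
    """
    n = embedding.shape[0]
    if cell_ids is None:
        cell_ids = np.asarray([f"cell{i}" for i in range(n)], dtype=str)
    W = snn_graph(embedding, n_neighbors=n_neighbors)
    tri = sp.triu(W, k=1).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(tri.row.tolist(), tri.col.tolist())),
                     edge_attrs={"weight": tri.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # canonical relabelling by order of first appearance
    _, first = np.unique(membership, return_index=True)
    relabel = {old: new for new, old in enumerate(membership[np.sort(first)])}
    labels = np.asarray([relabel[m] for m in membership])
    return ClusterAssignment(labels, cell_ids, {
        "resolution": resolution, "n_neighbors": n_neighbors, "seed": seed,
    })


def _redistribute(capacities: list[int], n_requested: int) -> list[int]:
    """Even allocation over capped pools (water filling).

    Small pools contribute everything they have; the deficit spreads evenly
    over the pools with spare capacity, so all non-exhausted pools end
    within one cell of each other.  The single-cell remainder goes to the
    lowest pool ids.
    """
    if n_requested > sum(capacities):
        raise ValueError(
            f"requested {n_requested} cells but only {sum(capacities)} available"
        )
    # find the fill level T with sum(min(cap, T)) <= n_requested
    level, top = 0, max(capacities)
    while level < top and sum(min(c, level + 1) for c in capacities) <= n_requested:
        level += 1
    alloc = [min(c, level) for c in capacities]
    remaining = n_requested - sum(alloc)
    for i in range(len(capacities)):
        if remaining == 0:
            break
        if capacities[i] > level:
            alloc[i] += 1
            remaining -= 1
    return alloc


def _sample_pools(pools: list[np.ndarray], quotas: list[int],
                  seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = []
    for pool, q in zip(pools, quotas):
        pool = np.sort(pool)  # deterministic order before the seeded draw
        out.append(rng.choice(pool, size=q, replace=False))
    return np.concatenate(out) if out else np.asarray([], dtype=str)


def sample_even_by_cluster(ca: ClusterAssignment, n_requested: int,
                           seed: int = 0) -> SelectionResult:
    """Naive adaptive reweighting: equal quotas per cluster."""
    pools = [ca.cell_ids[ca.cluster_ids == c] for c in range(ca.n_clusters)]
    quotas = _redistribute([len(p) for p in pools], n_requested)
    chosen = _sample_pools(pools, quotas, seed)
    return SelectionResult(chosen, "ar_naive",
                           {"n": n_requested, "seed": seed, **ca.params})


def assign_clusters_to_types(ds: ExpressionDataset, ca: ClusterAssignment,
                             spec: MarkerSpec) -> ClusterTypeMap:
    """Assign each cluster the type whose markers it is most enriched for.

    Enrichment(cluster, type) = mean over the cluster's cells of the mean
    positive-marker expression, minus the same quantity for the negative
    markers when any are given.  Computed on the lognorm/arcsinh scale.
    Argmax ties break by marker-file type order.
    """
    pos_scores = score_cells_by_markers(ds, spec)
    neg_cols = np.zeros((ds.n_cells, len(spec.types)))
    feat_index = pd.Index(ds.feature_ids)
    for j, t in enumerate(spec.types):
        present = [m for m in spec.negative[t] if m in feat_index]
        if present:
            cols = feat_index.get_indexer(present)
            neg_cols[:, j] = np.asarray(ds.values[:, cols].mean(axis=1)).ravel()
    per_cell = pos_scores.scores - neg_cols
    enrichment = np.vstack([
        per_cell[ca.cluster_ids == c].mean(axis=0) for c in range(ca.n_clusters)
    ])
    assigned = {c: spec.types[int(np.argmax(enrichment[c]))]
                for c in range(ca.n_clusters)}
    unassigned = set(spec.types) - set(assigned.values())
    if unassigned:
        logger.warning("cell types winning no cluster: %s", sorted(unassigned))
    return ClusterTypeMap(enrichment=enrichment, types=list(spec.types),
                          assigned_type=assigned)


def sample_even_by_type(ctm: ClusterTypeMap, ca: ClusterAssignment,
                        n_requested: int, seed: int = 0) -> SelectionResult:
    """Marker-aware adaptive reweighting: equal quotas per assigned type.

    A type's pool is the union of the clusters assigned to it; quotas use
    the same deficit-redistribution rule as the naive variant.
    """
    winner_types = [t for t in ctm.types if t in set(ctm.assigned_type.values())]
    if not winner_types:
        raise ValueError("no cluster was assigned to any cell type")
    pools = []
    for t in winner_types:
        clusters = [c for c, at in ctm.assigned_type.items() if at == t]
        mask = np.isin(ca.cluster_ids, clusters)
        pools.append(ca.cell_ids[mask])
    quotas = _redistribute([len(p) for p in pools], n_requested)
    chosen = _sample_pools(pools, quotas, seed)
    return SelectionResult(chosen, "ar_marker",
                           {"n": n_requested, "seed": seed, **ca.params})
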