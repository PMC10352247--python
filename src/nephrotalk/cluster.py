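"""Dimensionality reduction, graph clustering and marker-based annotation.

Clustering follows the standard single-cell workflow: highly variable gene
selection, PCA on the standardized HVG submatrix, a shared-nearest-neighbor
(SNN) graph in PC space, and Leiden community detection at a fixed
resolution.  Annotation scores each cluster against a marker table using the
mean z-score of cluster-mean marker expression; a cluster whose best score
is still below zero stays "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .qc import NormalizedMatrix

DEFAULT_N_HVG = 2000
DEFAULT_N_COMPONENTS = 30
DEFAULT_K_NEIGHBORS = 15
DEFAULT_RESOLUTION = 0.5


@dataclass
class MarkerTable:
    """cell type -> list of marker gene symbols."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.markers.values()):
            raise ValueError("marker lists must be non-empty")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerTable":
        return cls(
            {
                str(r.cell_type): [m.strip() for m in str(r.markers).split(",") if m.strip()]
                for r in df.itertuples(index=False)
            }
        )


@dataclass
class ClusterLabeling:
    """Per-cell cluster ids (dense ints from 0) plus cluster annotations."""

    cell_to_cluster: pd.Series  # index = cell ids, values = int cluster
    cluster_to_type: dict[int, str] = field(default_factory=dict)
    resolution: float = DEFAULT_RESOLUTION
    seed: int = 0

    @property
    def clusters(self) -> list[int]:
        return sorted(set(int(c) for c in self.cell_to_cluster))

    def cells_of(self, cluster: int) -> list[str]:
        return self.cell_to_cluster.index[self.cell_to_cluster == cluster].tolist()

    def type_of(self, cluster: int) -> str:
        return self.cluster_to_type.get(int(cluster), "unassigned")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.cell_to_cluster})
        df["cell_type"] = [self.type_of(c) for c in df["cluster"]]
        df.index.name = "cell_id"
        return df


def select_hvg(norm: NormalizedMatrix, n_top: int = DEFAULT_N_HVG) -> list[str]:
    """The n_top genes with highest variance of normalized expression.

    Ties are broken lexicographically by symbol so selection is deterministic.
    """
    n_top = min(n_top, norm.n_genes)
    var = norm.values.var(axis=0, ddof=1) if norm.n_cells > 1 else np.zeros(norm.n_genes)
    order = sorted(range(norm.n_genes), key=lambda i: (-var[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n_top]]


def embed_pca(
    norm: NormalizedMatrix,
    genes: list[str] | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
    scale: bool = True,
) -> np.ndarray:
    """PCA scores of the (optionally gene-subset) normalized matrix.

    With ``scale`` (the default, as in the standard single-cell workflow)
    genes are z-scored first so no single high-variance program dominates
    the embedding.  Columns are ordered by decreasing explained variance.
    Signs are fixed by requiring each component's largest-magnitude loading
    to be positive, so the embedding is fully deterministic.
    """
    if norm.n_cells < 2:
        raise ValueError("PCA needs at least two cells")
    X = norm.values
    if genes is not None:
        idx = [norm.gene_ids.index(g) for g in genes]
        X = X[:, idx]
    if scale:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(pca.components_.shape[0]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
            pca.components_[j] *= -1.0
    return scores


def snn_graph(embedding: np.ndarray, k_neighbors: int = DEFAULT_K_NEIGHBORS) -> ig.Graph:
    """Shared-nearest-neighbor graph; edge weight = |shared kNN| / k."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < n_cells ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row) for row in idx]  # includes self
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[j])
            if shared:
                edges.append((i, j))
                weights.append(shared / (k_neighbors + 1))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.simplify(combine_edges="max")
    return g


def cluster_cells(
    embedding: np.ndarray,
    cell_ids: list[str],
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> ClusterLabeling:
    """Leiden community detection on the SNN graph, deterministic per seed.

    Cluster ids are relabeled to dense integers ordered by decreasing size
    (ties by smallest member index), which also makes the labeling invariant
    to cell-order permutations up to relabeling.
    """
    g = snn_graph(embedding, k_neighbors=k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"],
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    order = sorted(
        set(raw), key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0]))
    )
    remap = {c: i for i, c in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=pd.Index(cell_ids, name="cell_id"), dtype=int
    )
    return ClusterLabeling(cell_to_cluster=labels, resolution=resolution, seed=seed)


def annotate_clusters(
    labels: ClusterLabeling,
    norm: NormalizedMatrix,
    markers: MarkerTable,
) -> ClusterLabeling:
    """Assign each cluster the cell type with the highest marker score.

    Score = mean over the type's marker genes of the z-score (across
    clusters) of cluster-mean normalized expression.  All scores < 0 =>
    "unassigned".  Ties break lexicographically by type name; missing marker
    genes are dropped with a warning.
    """
    if not markers.markers:
        raise ValueError("empty marker table")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    clusters = labels.clusters
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    cluster_rows = {
        k: np.array([cell_pos[c] for c in labels.cells_of(k) if c in cell_pos])
        for k in clusters
    }
    # cluster-mean expression, then per-gene z-score across clusters
    means = np.vstack(
        [norm.values[cluster_rows[k]].mean(axis=0) for k in clusters]
    )  # clusters x genes
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    assignment: dict[int, str] = {}
    for ci, k in enumerate(clusters):
        best_type, best_score = "unassigned", 0.0
        for cell_type in sorted(markers.markers):
            idx = []
            for m in markers.markers[cell_type]:
                if m in gene_pos:
                    idx.append(gene_pos[m])
                else:
                    warnings.warn(f"marker {m!r} not in matrix; dropped", stacklevel=2)
            if not idx:
                continue
            score = float(z[ci, idx].mean())
            if score > best_score:
                best_type, best_score = cell_type, score
        assignment[int(k)] = best_type
    return ClusterLabeling(
        cell_to_cluster=labels.cell_to_cluster.copy(),
        cluster_to_type=assignment,
        resolution=labels.resolution,
        seed=labels.seed,
    )


def cluster_composition(labels: ClusterLabeling, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Cell counts and percentages per cluster x condition.

    Percentages sum to 100 within each condition.
    """
    df = pd.DataFrame(
        {
            "cluster": labels.cell_to_cluster,
            "condition": cell_meta.loc[labels.cell_to_cluster.index, "condition"],
        }
    )
    counts = df.groupby(["cluster", "condition"], observed=True).size().rename("n_cells")
    out = counts.reset_index()
    totals = out.groupby("condition")["n_cells"].transform("sum")
    out["percentage"] = 100.0 * out["n_cells"] / totals
    out["cell_type"] = [labels.type_of(c) for c in out["cluster"]]
    return out


def sub_cluster(
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    cell_type: str,
    resolution: float = DEFAULT_RESOLUTION,
    n_hvg: int = DEFAULT_N_HVG,
    n_components: int = DEFAULT_N_COMPONENTS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> ClusterLabeling:
    """Re-cluster the cells of one annotated type with its own resolution."""
    keep = [
        c
        for c in norm.cell_ids
        if labels.type_of(int(labels.cell_to_cluster[c])) == cell_type
    ]
    if len(keep) <= k_neighbors:
        raise ValueError(f"too few {cell_type!r} cells to sub-cluster")
    idx = [norm.cell_ids.index(c) for c in keep]
    sub = NormalizedMatrix(
        values=norm.values[idx],
        cell_ids=keep,
        gene_ids=list(norm.gene_ids),
        cell_meta=norm.cell_meta.loc[keep].copy(),
        scale_factor=norm.scale_factor,
    )
    hvg = select_hvg(sub, n_hvg)
    emb = embed_pca(sub, hvg, n_components)
    return cluster_cells(emb, keep, k_neighbors, resolution, seed)
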