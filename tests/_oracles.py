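"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over cells/genes, deliberately
avoiding the vectorized code paths of the package under test.
"""

import numpy as np
import pandas as pd
import scipy.sparse as sp

from nephrotalk.io import CountMatrix, LRPair
from nephrotalk.cluster import ClusterLabeling
from nephrotalk.qc import normalize_log


def naive_qc_metrics(counts):
    """Per-cell loop over the dense matrix."""
    X = np.asarray(counts.values.todense())
    mito = counts.gene_meta["is_mito"].to_numpy()
    rows = []
    for i in range(X.shape[0]):
        n_feat = sum(1 for v in X[i] if v > 0)
        total = int(X[i].sum())
        mito_total = int(X[i][mito].sum()) if mito.any() else 0
        frac = mito_total / total if total > 0 else 0.0
        rows.append((n_feat, total, frac))
    return rows


def naive_qc_survivors(metrics, min_features, max_features, max_mito):
    """Literal enumeration of the keep rule."""
    keep = []
    for cell, row in metrics.iterrows():
        if row["n_features"] < min_features:
            continue
        if row["n_features"] > max_features:
            continue
        if row["mito_fraction"] > max_mito:
            continue
        keep.append(cell)
    return keep


def naive_tom(A):
    """Triple-loop topological overlap of an adjacency matrix."""
    n = A.shape[0]
    T = np.eye(n)
    k = [sum(A[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


def naive_crosstalk(counts, norm, labels, db, min_fraction, min_fc, eps=0.01):
    """Literal application of criteria C1-C3 as nested loops.

    Returns the set of (sender, receiver, ligand, receptor) keys.  Assumes
    every cluster has cells in both conditions.
    """
    pairs = sorted({(p.ligand, p.receptor) for p in db})
    gene_pos = {g: j for j, g in enumerate(counts.gene_ids)}
    cell_pos = {c: i for i, c in enumerate(counts.cell_ids)}
    raw = np.asarray(counts.values.todense())
    expr = np.expm1(norm.values)
    nexpr_pos = {c: i for i, c in enumerate(norm.cell_ids)}

    def cells(cluster, cond):
        return [
            c
            for c in labels.cells_of(cluster)
            if counts.cell_meta.loc[c, "condition"] == cond
        ]

    def fraction(gene, cluster):
        group = cells(cluster, "case")
        if gene not in gene_pos:
            return 0.0
        hits = sum(1 for c in group if raw[cell_pos[c], gene_pos[gene]] > 0)
        return hits / len(group)

    def mean(gene, cluster, cond):
        group = cells(cluster, cond)
        if gene not in gene_pos:
            return 0.0
        vals = [expr[nexpr_pos[c], gene_pos[gene]] for c in group]
        return sum(vals) / len(vals)

    keys = set()
    for s in labels.clusters:
        for r in labels.clusters:
            for lig, rec in pairs:
                if fraction(lig, s) < min_fraction:
                    continue
                if fraction(rec, r) < min_fraction:
                    continue
                fc = (mean(lig, s, "case") + eps) / (mean(lig, s, "control") + eps)
                if fc < min_fc:
                    continue
                if not (mean(lig, s, "case") > 0 and mean(rec, r, "case") > 0):
                    continue
                keys.add((s, r, lig, rec))
    return keys


def random_crosstalk_instance(rng):
    """A small random (counts, norm, labels, db) instance.

    At most 5 clusters and 50 database pairs; every cluster has cells in both
    conditions; some database genes are absent from the matrix.
    """
    n_clusters = int(rng.integers(2, 6))
    n_genes = int(rng.integers(8, 21))
    gene_ids = [f"G{j}" for j in range(n_genes)]
    cell_ids, conds, labels_list = [], [], []
    for k in range(n_clusters):
        for cond in ("control", "case"):
            for j in range(int(rng.integers(3, 9))):
                cell_ids.append(f"k{k}_{cond}_{j}")
                conds.append(cond)
                labels_list.append(k)
    n_cells = len(cell_ids)
    lam = rng.uniform(0.05, 3.0, size=(1, n_genes)) * rng.uniform(
        0.3, 2.5, size=(n_cells, 1)
    )
    X = rng.poisson(lam)
    X[:, 0] += 1  # keep every cell's total positive
    counts = CountMatrix(
        values=sp.csr_matrix(X),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame(
            {"sample": "s0", "condition": conds}, index=pd.Index(cell_ids)
        ),
        gene_meta=pd.DataFrame(
            {"is_mito": [False] * n_genes}, index=pd.Index(gene_ids)
        ),
    )
    norm = normalize_log(counts)
    labels = ClusterLabeling(
        cell_to_cluster=pd.Series(
            labels_list, index=pd.Index(cell_ids, name="cell_id"), dtype=int
        )
    )
    pool = gene_ids + ["ZZ0", "ZZ1"]  # ZZ genes are absent from the matrix
    n_pairs = int(rng.integers(4, 51))
    db = [
        LRPair(
            ligand=pool[int(rng.integers(len(pool)))],
            receptor=pool[int(rng.integers(len(pool)))],
            source="rand",
        )
        for _ in range(n_pairs)
    ]
    return counts, norm, labels, db
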