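"""Ligand-receptor cross-talk inference between annotated cell clusters.

A candidate interaction is an ordered (sender, receiver) cluster pair and a
database ligand-receptor pair.  An edge is emitted only when, in the case
condition, all three criteria hold:

  C1  the ligand is detected (raw count > 0) in at least ``min_fraction`` of
      the sender cluster's cells, and the receptor in at least
      ``min_fraction`` of the receiver cluster's cells;
  C2  the ligand's case-vs-control fold change in the sender cluster is at
      least ``min_fc`` (ratio of de-logged normalized means with a fixed
      pseudocount);
  C3  the ligand has nonzero mean expression in the sender and the receptor
      nonzero mean expression in the receiver.

Defaults are min_fraction = 0.5 and min_fc = 2 (inclusive).  Self pairs
(sender == receiver) are allowed.  Output order is deterministic:
(sender, receiver, ligand, receptor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterLabeling
from .de import PSEUDOCOUNT
from .io import CountMatrix, LRPair
from .qc import NormalizedMatrix

DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MIN_FC = 2.0


@dataclass(frozen=True)
class InteractionEdge:
    """An accepted sender -> receiver ligand-receptor interaction."""

    ligand: str
    receptor: str
    sender_cluster: object
    receiver_cluster: object
    ligand_fraction_sender: float
    receptor_fraction_receiver: float
    ligand_fc: float
    condition_scope: str = "case"

    @property
    def key(self) -> tuple:
        return (self.sender_cluster, self.receiver_cluster, self.ligand, self.receptor)


def _cluster_condition_cells(
    counts: CountMatrix, labels: ClusterLabeling, cluster, condition: str
) -> np.ndarray:
    pos = {c: i for i, c in enumerate(counts.cell_ids)}
    cells = [
        c
        for c in labels.cells_of(cluster)
        if c in pos and counts.cell_meta.loc[c, "condition"] == condition
    ]
    return np.array([pos[c] for c in cells], dtype=int)


def expression_fraction(
    counts: CountMatrix,
    labels: ClusterLabeling,
    gene: str,
    cluster,
    condition: str = "case",
) -> float:
    """Fraction of the cluster-condition's cells with raw count > 0.

    An absent gene counts as undetected everywhere (0.0, with a warning);
    an empty cluster-condition group is an error.
    """
    idx = _cluster_condition_cells(counts, labels, cluster, condition)
    if idx.size == 0:
        raise ValueError(f"cluster {cluster} has no cells in condition {condition!r}")
    try:
        j = counts.gene_index(gene)
    except KeyError:
        warnings.warn(f"gene {gene!r} absent from matrix; fraction 0", stacklevel=2)
        return 0.0
    col = counts.values[idx, j]
    detected = int((col > 0).sum())
    return detected / idx.size


def _group_mean(norm: NormalizedMatrix, labels: ClusterLabeling, gene: str,
                cluster, condition: str) -> float:
    pos = {c: i for i, c in enumerate(norm.cell_ids)}
    cells = [
        c
        for c in labels.cells_of(cluster)
        if c in pos and norm.cell_meta.loc[c, "condition"] == condition
    ]
    if not cells:
        raise ValueError(f"cluster {cluster} has no cells in condition {condition!r}")
    if gene not in norm.gene_ids:
        return 0.0
    j = norm.gene_ids.index(gene)
    idx = [pos[c] for c in cells]
    return float(np.expm1(norm.values[idx, j]).mean())


def ligand_fold_change(
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    gene: str,
    cluster,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """(mean_case + eps) / (mean_control + eps) on the de-logged scale."""
    mean_case = _group_mean(norm, labels, gene, cluster, "case")
    mean_ctrl = _group_mean(norm, labels, gene, cluster, "control")
    return (mean_case + pseudocount) / (mean_ctrl + pseudocount)


def infer_interactions(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    lr_db: list[LRPair],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_fc: float = DEFAULT_MIN_FC,
    pseudocount: float = PSEUDOCOUNT,
) -> list[InteractionEdge]:
    """Apply criteria C1-C3 to every (sender, receiver, LR pair) candidate.

    Fractions and means are evaluated in the case condition; the fold change
    compares case to control within the sender cluster.  Results are sorted
    by (sender, receiver, ligand, receptor) and do not depend on database
    row order or cell order.
    """
    if not lr_db:
        warnings.warn("empty ligand-receptor database", stacklevel=2)
        return []
    pairs = sorted({p.key for p in lr_db})
    genes = sorted({g for lg, rc in pairs for g in (lg, rc)})

    # a sender needs both conditions (for the fold change); a receiver only
    # needs case cells
    conditions = counts.cell_meta["condition"]
    clusters = []
    senders_ok = set()
    for k in labels.clusters:
        conds = set(conditions[c] for c in labels.cells_of(k) if c in conditions.index)
        if "case" in conds:
            clusters.append(k)
            if "control" in conds:
                senders_ok.add(k)
            else:
                warnings.warn(
                    f"cluster {k} has no control cells; excluded as sender",
                    stacklevel=2,
                )
        else:
            warnings.warn(
                f"cluster {k} has no case cells; excluded from cross-talk",
                stacklevel=2,
            )

    # precompute per (gene, cluster): case fraction, case mean, fold change
    frac: dict[tuple[str, object], float] = {}
    case_mean: dict[tuple[str, object], float] = {}
    fc: dict[tuple[str, object], float] = {}
    warned: set[str] = set()
    for k in clusters:
        for g in genes:
            if g not in counts.gene_ids:
                if g not in warned:
                    warnings.warn(
                        f"gene {g!r} absent from matrix; treated as undetected",
                        stacklevel=2,
                    )
                    warned.add(g)
                frac[(g, k)] = 0.0
                case_mean[(g, k)] = 0.0
                fc[(g, k)] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frac[(g, k)] = expression_fraction(counts, labels, g, k, "case")
            case_mean[(g, k)] = _group_mean(norm, labels, g, k, "case")
            fc[(g, k)] = (
                ligand_fold_change(norm, labels, g, k, pseudocount)
                if k in senders_ok
                else 0.0
            )

    edges: list[InteractionEdge] = []
    for sender in clusters:
        if sender not in senders_ok:
            continue
        for receiver in clusters:
            for ligand, receptor in pairs:
                lf = frac[(ligand, sender)]
                rf = frac[(receptor, receiver)]
                if lf < min_fraction or rf < min_fraction:
                    continue  # C1
                lfc = fc[(ligand, sender)]
                if lfc < min_fc:
                    continue  # C2
                if not (case_mean[(ligand, sender)] > 0 and case_mean[(receptor, receiver)] > 0):
                    continue  # C3
                edges.append(
                    InteractionEdge(
                        ligand=ligand,
                        receptor=receptor,
                        sender_cluster=sender,
                        receiver_cluster=receiver,
                        ligand_fraction_sender=lf,
                        receptor_fraction_receiver=rf,
                        ligand_fc=lfc,
                    )
                )
    edges.sort(key=lambda e: (str(e.sender_cluster), str(e.receiver_cluster), e.ligand, e.receptor))
    return edges


def interaction_summary(edges: list[InteractionEdge]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge counts per ordered cluster pair and per-ligand totals
    (ligands ranked by number of edges, ties by symbol)."""
    if not edges:
        empty_pairs = pd.DataFrame(columns=["sender_cluster", "receiver_cluster", "n_edges"])
        empty_lig = pd.DataFrame(columns=["ligand", "n_edges"])
        return empty_pairs, empty_lig
    df = pd.DataFrame(
        [
            {
                "sender_cluster": e.sender_cluster,
                "receiver_cluster": e.receiver_cluster,
                "ligand": e.ligand,
            }
            for e in edges
        ]
    )
    pair_counts = (
        df.groupby(["sender_cluster", "receiver_cluster"], observed=True)
        .size()
        .rename("n_edges")
        .reset_index()
    )
    ligand_counts = (
        df.groupby("ligand").size().rename("n_edges").reset_index()
        .sort_values(["n_edges", "ligand"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return pair_counts, ligand_counts
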