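"""Per-cluster case-vs-control differential expression.

The test is a two-sided Wilcoxon rank-sum (Mann-Whitney U) with the
tie-corrected normal approximation, Benjamini-Hochberg adjusted within each
cluster.  Fold changes are ratios of de-logged normalized group means with a
fixed pseudocount, so "fold change >= 2" reads as a ratio of expression
levels rather than a difference of logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterLabeling
from .qc import NormalizedMatrix

# pseudocount on the de-logged (counts-per-scale_factor) scale; shared with
# the crosstalk fold-change criterion
PSEUDOCOUNT = 0.01

MIN_CELLS_PER_GROUP = 3


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    cluster: int
    log2_fc: float
    p_value: float
    adj_p: float
    mean_case: float
    mean_control: float


def group_means(
    norm: NormalizedMatrix, labels: ClusterLabeling, condition: str
) -> pd.DataFrame:
    """Mean de-logged normalized expression per (cluster, gene) in one condition.

    Empty (cluster, condition) groups are excluded and listed in the
    frame's ``attrs["empty_clusters"]``.
    """
    cond_mask = (norm.cell_meta["condition"] == condition).to_numpy()
    expr = norm.expm1()
    rows = {}
    empty = []
    cl = labels.cell_to_cluster.loc[norm.cell_ids].to_numpy()
    for k in labels.clusters:
        mask = cond_mask & (cl == k)
        if mask.sum() == 0:
            empty.append(k)
            continue
        rows[k] = expr[mask].mean(axis=0)
    out = pd.DataFrame(rows, index=pd.Index(norm.gene_ids, name="gene")).T
    out.index.name = "cluster"
    out.attrs["empty_clusters"] = empty
    return out


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided tie-corrected normal-approximation rank-sum p-value."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values tied: no evidence either way
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    return float(res.pvalue)


def rank_sum_deg(
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    cluster: int,
    pseudocount: float = PSEUDOCOUNT,
) -> list[DEGRecord]:
    """Case-vs-control DE for every gene within one cluster.

    Requires at least MIN_CELLS_PER_GROUP cells per condition.  p-values are
    BH-adjusted within the cluster; log2 fold change uses de-logged means
    with the module pseudocount.
    """
    cells = labels.cells_of(cluster)
    pos = {c: i for i, c in enumerate(norm.cell_ids)}
    idx = np.array([pos[c] for c in cells if c in pos])
    cond = norm.cell_meta.iloc[idx]["condition"].to_numpy()
    case_idx = idx[cond == "case"]
    ctrl_idx = idx[cond == "control"]
    if len(case_idx) < MIN_CELLS_PER_GROUP or len(ctrl_idx) < MIN_CELLS_PER_GROUP:
        raise ValueError(
            f"cluster {cluster}: need >= {MIN_CELLS_PER_GROUP} cells per condition, "
            f"got case={len(case_idx)}, control={len(ctrl_idx)}"
        )
    case = np.expm1(norm.values[case_idx])
    ctrl = np.expm1(norm.values[ctrl_idx])
    mean_case = case.mean(axis=0)
    mean_ctrl = ctrl.mean(axis=0)
    pvals = np.array(
        [_rank_sum_p(case[:, j], ctrl[:, j]) for j in range(norm.n_genes)]
    )
    adj = multipletests(pvals, method="fdr_bh")[1]
    log2_fc = np.log2((mean_case + pseudocount) / (mean_ctrl + pseudocount))
    return [
        DEGRecord(
            gene=norm.gene_ids[j],
            cluster=int(cluster),
            log2_fc=float(log2_fc[j]),
            p_value=float(pvals[j]),
            adj_p=float(adj[j]),
            mean_case=float(mean_case[j]),
            mean_control=float(mean_ctrl[j]),
        )
        for j in range(norm.n_genes)
    ]


def deg_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
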