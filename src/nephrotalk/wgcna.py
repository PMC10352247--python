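"""Weighted co-expression module detection over cell groups.

The network is built the WGCNA way: pseudocell aggregation to tame
single-cell sparsity, an unsigned adjacency a_ij = |cor(g_i, g_j)|^beta with
beta selected by the scale-free topology criterion, topological overlap
similarity, average-linkage hierarchical clustering of 1 - TOM with a static
cut, module eigengenes (PC1 of the standardized module submatrix), Pearson
module-trait correlation, and kME hub ranking.  Everything here is
deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .cluster import ClusterLabeling
from .qc import NormalizedMatrix

DEFAULT_GROUP_SIZE = 10
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_TOP_K_HUBS = 25
DEFAULT_SCALE_FREE_R2 = 0.80
GREY = "grey"


@dataclass
class ModuleSet:
    """Result of module detection plus downstream summaries."""

    beta: float
    gene_to_module: dict[str, str]  # gene -> "M1", "M2", ... or "grey"
    dendrogram: np.ndarray  # scipy linkage matrix
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # obs x module
    module_trait_r: pd.DataFrame = field(default_factory=pd.DataFrame)
    module_trait_p: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def modules(self) -> list[str]:
        mods = {m for m in self.gene_to_module.values() if m != GREY}
        return sorted(mods, key=lambda m: int(m[1:]))

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.gene_to_module.items() if m == module]


@dataclass
class HubRanking:
    module: str
    genes: list[tuple[str, float]]  # (gene, kME), decreasing kME


def aggregate_pseudocells(
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    group_size: int = DEFAULT_GROUP_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Average non-overlapping groups of same-cluster same-condition cells.

    Rows are pseudocell observations (index ``<cluster>|<condition>|<g>``),
    columns genes; the frame's ``attrs["obs_meta"]`` carries the (cluster,
    condition) of every observation.  group_size = 1 is the identity.
    Only full groups are kept: a trailing partial group, or a
    cluster-condition stratum smaller than group_size, is dropped, so tiny
    stray clusters cannot contribute high-leverage observations to the
    gene-gene correlations.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    pos = {c: i for i, c in enumerate(norm.cell_ids)}
    obs_rows = []
    meta_rows = []
    conditions = norm.cell_meta["condition"]
    for k in labels.clusters:
        for cond in ("control", "case"):
            cells = [
                c
                for c in labels.cells_of(k)
                if c in pos and conditions[c] == cond
            ]
            if len(cells) < group_size:
                continue
            order = rng.permutation(len(cells))
            n_full = len(cells) // group_size
            for gi, start in enumerate(range(0, n_full * group_size, group_size)):
                members = order[start : start + group_size]
                rows = [pos[cells[i]] for i in members]
                obs_rows.append(norm.values[rows].mean(axis=0))
                meta_rows.append(
                    {"obs": f"{k}|{cond}|{gi}", "cluster": k, "condition": cond}
                )
    obs = pd.DataFrame(
        np.vstack(obs_rows),
        index=pd.Index([m["obs"] for m in meta_rows], name="obs"),
        columns=norm.gene_ids,
    )
    obs.attrs["obs_meta"] = pd.DataFrame(meta_rows).set_index("obs")
    return obs


def _connectivity(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) on log10 k over equal-width k bins.

    Positive slope (anti-scale-free) yields a negative index, as in the
    standard scale-free topology fit.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        # singleton bins carry no frequency information and destabilize the
        # regression; skip them
        if members.size < 2:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        return 0.0
    x, y = np.array(log_k), np.array(log_p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    r2_target: float = DEFAULT_SCALE_FREE_R2,
) -> int:
    """Smallest candidate power whose scale-free fit reaches r2_target,
    else the power maximizing the fit."""
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    powers = list(candidate_powers) if candidate_powers else list(range(1, 21))
    cor = np.abs(_pearson_matrix(expr.to_numpy()))
    best_power, best_fit = powers[0], -np.inf
    for p in powers:
        adj = cor**p
        fit = scale_free_fit(_connectivity(adj))
        if fit >= r2_target:
            return p
        if fit > best_fit:
            best_power, best_fit = p, fit
    return best_power


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation across columns; constant columns are rejected."""
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant gene reached correlation stage")
    C = np.corrcoef(X, rowvar=False)
    return np.clip(C, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor|^beta (diag = 1)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = np.abs(_pearson_matrix(expr.to_numpy())) ** beta
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    return pd.DataFrame(A, index=expr.columns, columns=expr.columns)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diag 1."""
    A = adj.to_numpy(dtype=float)
    k = A.sum(axis=1) - np.diag(A)
    L = A @ A
    # remove u = i and u = j terms from the neighbor sum
    L = L - np.diag(A)[:, None] * A - A * np.diag(A)[None, :]
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> tuple[dict[str, str], np.ndarray]:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Branches below ``cut_height`` with at least ``min_module_size`` members
    become modules "M1", "M2", ... ordered by decreasing size (ties by the
    lexicographically smallest member gene); everything else is "grey".
    """
    genes = list(tom.columns)
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=cut_height, criterion="distance")
    branches: dict[int, list[str]] = {}
    for g, b in zip(genes, flat):
        branches.setdefault(int(b), []).append(g)
    keep = [b for b, members in branches.items() if len(members) >= min_module_size]
    keep.sort(key=lambda b: (-len(branches[b]), min(branches[b])))
    assignment = {g: GREY for g in genes}
    for mi, b in enumerate(keep, start=1):
        for g in branches[b]:
            assignment[g] = f"M{mi}"
    return assignment, Z


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First-PC scores of the standardized module submatrix, sign-aligned so
    that cor(eigengene, mean module expression) >= 0."""
    if not module_genes:
        raise ValueError("module is empty")
    if expr.shape[0] < 2:
        raise ValueError("eigengene needs >= 2 observations")
    X = expr[module_genes].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    # PC1 via SVD of the standardized submatrix
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    mean_profile = X.mean(axis=1)
    if np.std(mean_profile) > 0 and np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.index, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, gene_to_module: dict[str, str]) -> pd.DataFrame:
    mods = sorted(
        {m for m in gene_to_module.values() if m != GREY}, key=lambda m: int(m[1:])
    )
    return pd.DataFrame(
        {
            m: module_eigengene(expr, [g for g, mm in gene_to_module.items() if mm == m])
            for m in mods
        }
    )


def trait_indicators(obs_meta: pd.DataFrame) -> pd.DataFrame:
    """Binary (cluster x condition) indicator traits over observations."""
    cols = {}
    for k in sorted(obs_meta["cluster"].unique()):
        for cond in ("control", "case"):
            name = f"cluster{k}_{cond}"
            cols[name] = (
                (obs_meta["cluster"] == k) & (obs_meta["condition"] == cond)
            ).astype(float)
    return pd.DataFrame(cols, index=obs_meta.index)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (with two-sided t-distribution p) per module x trait.

    Constant traits yield NaN (undefined correlation)."""
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy()
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            if np.ptp(tv) == 0 or np.ptp(e) == 0:
                r.loc[m, t] = np.nan
                p.loc[m, t] = np.nan
                continue
            rr, pp = pearsonr(e, tv)
            r.loc[m, t] = rr
            p.loc[m, t] = pp
    return r, p


def hub_genes(
    expr: pd.DataFrame,
    eigengene: pd.Series,
    module_genes: list[str],
    top_k: int = DEFAULT_TOP_K_HUBS,
) -> HubRanking:
    """Rank module genes by kME = cor(gene profile, eigengene); top_k kept,
    ties broken lexicographically."""
    if not module_genes:
        raise ValueError("module is empty")
    e = eigengene.to_numpy(dtype=float)
    kme = {}
    for g in module_genes:
        x = expr[g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(e) == 0:
            kme[g] = 0.0
        else:
            kme[g] = float(np.corrcoef(x, e)[0, 1])
    ranked = sorted(kme.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    name = getattr(eigengene, "name", "module") or "module"
    return HubRanking(module=str(name), genes=ranked)


def run_module_analysis(
    norm: NormalizedMatrix,
    labels: ClusterLabeling,
    group_size: int = DEFAULT_GROUP_SIZE,
    candidate_powers: list[int] | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    seed: int = 0,
) -> tuple[ModuleSet, pd.DataFrame]:
    """Full module pipeline: pseudocells -> beta -> adjacency -> TOM ->
    modules -> eigengenes -> module-trait correlation.  Returns the
    ModuleSet and the pseudocell expression frame used."""
    expr = aggregate_pseudocells(norm, labels, group_size=group_size, seed=seed)
    # drop constant genes before correlation (recorded on the result)
    sd = expr.to_numpy().std(axis=0)
    dropped = [g for g, s in zip(expr.columns, sd) if s == 0]
    expr_used = expr.loc[:, sd > 0]
    expr_used.attrs["obs_meta"] = expr.attrs["obs_meta"]
    beta = pick_soft_threshold(expr_used, candidate_powers)
    adj = adjacency(expr_used, beta)
    tom = tom_similarity(adj)
    assignment, Z = detect_modules(tom, min_module_size, cut_height)
    for g in dropped:
        assignment[g] = GREY
    eig = module_eigengenes(expr_used, assignment)
    traits = trait_indicators(expr.attrs["obs_meta"])
    r, p = module_trait_correlation(eig, traits)
    ms = ModuleSet(
        beta=float(beta),
        gene_to_module=assignment,
        dendrogram=Z,
        eigengenes=eig,
        module_trait_r=r,
        module_trait_p=p,
    )
    return ms, expr_used
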