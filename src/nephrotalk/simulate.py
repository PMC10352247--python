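"""Two-condition single-cell count simulator with planted ground truth.

Emulates a control ("db/m"-like) vs case ("db/db"-like) kidney scRNA-seq
experiment: negative-binomial counts over a few thousand genes, clusters
distinguished by elevated marker genes named after canonical kidney cell
types, mouse-style mitochondrial genes ("mt-" prefix), a block of cells
constructed to violate QC thresholds, gene modules driven by a shared
per-cell latent factor, and ligand-receptor pairs whose ligand is
up-regulated in the case condition of a chosen sender cluster while the
receptor is constitutively detected in a receiver cluster.  Decoy pairs
break exactly one cross-talk filter criterion (fold change ~1 or detection
fraction far below one half).  Everything is reproducible bit-for-bit from
(params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster import ClusterLabeling, MarkerTable
from .io import CountMatrix, LRPair

# canonical kidney marker panels used to name the planted cluster markers
KIDNEY_MARKERS: dict[str, list[str]] = {
    "PT": ["AQP1", "LRP2", "SLC13A1"],
    "TAL": ["SLC12A1", "UMOD"],
    "DCT": ["SLC12A3", "SLC8A1"],
    "MCD": ["UPK1B", "UPK3A"],
    "podocyte": ["NPHS1", "NPHS2"],
    "EC": ["PECAM1", "CDH5"],
    "CD-IC": ["SLC26A4", "SCNN1A"],
    "CD-PC": ["AQP2", "FXYD4", "STC1"],
    "MC": ["PDGFRB", "CFH", "ZEB2", "COL12A1"],
}

MITO_GENE_NAMES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]


@dataclass(frozen=True)
class PlantedPair:
    """A planted (or decoy) ligand-receptor interaction."""

    ligand: str
    receptor: str
    sender_cluster: int
    receiver_cluster: int
    ligand_fc: float
    target_fraction: float

    @property
    def key(self) -> tuple:
        return (self.sender_cluster, self.receiver_cluster, self.ligand, self.receptor)


def default_true_pairs() -> list[PlantedPair]:
    """Twelve up-regulated pairs (fc 4, detection 0.9), including the named
    kidney axes; LRP2 doubles as PT marker and GC receptor, so GC targets
    the PT cluster."""
    named = [
        ("SPP1", "CD44", 1, 3),
        ("SPP1", "ITGAV", 1, 2),
        ("SEMA3C", "NRP1", 5, 4),
        ("SEMA3C", "NRP2", 5, 5),
        ("C3", "CD81", 2, 0),
        ("FGG", "ITGAV", 3, 2),
        ("GC", "LRP2", 4, 0),
    ]
    extra = [(f"Lig{i}", f"Rec{i}", i % 6, (i + 2) % 6) for i in range(1, 6)]
    return [
        PlantedPair(l, r, s, t, ligand_fc=4.0, target_fraction=0.9)
        for l, r, s, t in named + extra
    ]


def default_decoy_pairs() -> list[PlantedPair]:
    """Twenty decoys: ten with no case up-regulation (fc 1) and ten whose
    ligand is detected in only ~20% of sender cells."""
    flat = [
        PlantedPair(f"DecL{i}", f"DecR{i}", i % 6, (i + 3) % 6,
                    ligand_fc=1.0, target_fraction=0.9)
        for i in range(10)
    ]
    sparse = [
        PlantedPair(f"DecL{i}", f"DecR{i}", i % 6, (i + 3) % 6,
                    ligand_fc=4.0, target_fraction=0.2)
        for i in range(10, 20)
    ]
    return flat + sparse


@dataclass
class SimulationParams:
    """Generative settings; defaults define the standard study conditions."""

    n_clusters: int = 6
    cells_per_cluster_per_condition: int = 150
    n_genes: int = 1500
    n_mito_genes: int = 13
    marker_genes_per_cluster: int = 10
    marker_log2_effect: float = 2.0
    nb_dispersion: float = 0.1  # var = mu + disp * mu^2
    library_size_mean: float = 1.0  # multiplicative, log-normal
    library_size_sigma: float = 0.25
    base_mean_shape: float = 0.8  # gamma prior on baseline gene means
    base_mean_scale: float = 2.0
    marker_base_mean: float = 0.8
    module_gene_mean: float = 12.0
    mito_gene_mean: float = 15.0
    receptor_target_fraction: float = 0.9
    detection_margin: float = 1.4  # safety factor on detection-solved means
    planted_modules: list[tuple[int, float]] = field(
        default_factory=lambda: [(50, 1.2), (50, 1.2), (50, 1.2)]
    )
    true_lr_pairs: list[PlantedPair] = field(default_factory=default_true_pairs)
    decoy_lr_pairs: list[PlantedPair] = field(default_factory=default_decoy_pairs)
    n_low_quality_cells: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_clusters", "cells_per_cluster_per_condition", "n_genes",
            "n_mito_genes", "marker_genes_per_cluster", "n_low_quality_cells",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library size must be positive")
        if sum(size for size, _ in self.planted_modules) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        for p in self.true_lr_pairs + self.decoy_lr_pairs:
            if not (0.0 <= p.target_fraction <= 1.0):
                raise ValueError(f"target_fraction out of [0,1] for {p.ligand}")
            if p.ligand_fc <= 0:
                raise ValueError(f"ligand_fc must be positive for {p.ligand}")
            if max(p.sender_cluster, p.receiver_cluster) >= self.n_clusters:
                raise ValueError(f"cluster out of range for {p.ligand}-{p.receptor}")
        lr_genes = [g for p in self.true_lr_pairs + self.decoy_lr_pairs
                    for g in (p.ligand, p.receptor)]
        ligands = {p.ligand for p in self.true_lr_pairs + self.decoy_lr_pairs}
        dup = ligands & {p.receptor for p in self.true_lr_pairs + self.decoy_lr_pairs}
        if dup:
            raise ValueError(f"genes used as both ligand and receptor: {sorted(dup)}")


@dataclass
class SyntheticTruth:
    """Everything planted, for downstream recovery checks."""

    cell_to_cluster: dict[str, int]
    gene_to_module: dict[str, str]  # only module member genes listed
    true_interactions: set[tuple]
    decoy_interactions: set[tuple]
    qc_fail_cells: set[str]

    def labeling(self, cell_ids: list[str] | None = None) -> ClusterLabeling:
        """Ground-truth labels as a ClusterLabeling (optionally subset)."""
        items = self.cell_to_cluster if cell_ids is None else {
            c: self.cell_to_cluster[c] for c in cell_ids
        }
        return ClusterLabeling(
            cell_to_cluster=pd.Series(items, dtype=int).rename_axis("cell_id")
        )


def detection_mean(target_fraction: float, dispersion: float) -> float:
    """NB mean whose zero probability equals 1 - target_fraction.

    With var = mu + d*mu^2 the NB size is r = 1/d and
    P(0) = (r / (r + mu))^r, so mu = r((1-f)^(-1/r) - 1)."""
    if target_fraction <= 0:
        return 0.0
    if target_fraction >= 1:
        raise ValueError("target_fraction must be < 1 to solve for a finite mean")
    r = 1.0 / dispersion
    return r * ((1.0 - target_fraction) ** (-1.0 / r) - 1.0)


def default_marker_table(n_clusters: int = 6) -> MarkerTable:
    """Marker table matching the simulator's cluster -> cell-type layout."""
    types = list(KIDNEY_MARKERS)[:n_clusters]
    return MarkerTable({t: list(KIDNEY_MARKERS[t]) for t in types})


def _build_gene_table(params: SimulationParams) -> pd.DataFrame:
    """Assign names and roles to the n_genes slots.

    Order: mito genes, cluster markers, LR genes, module genes, background.
    A gene may be both a marker and an LR receptor (shared symbol)."""
    rows: list[dict] = []
    used: set[str] = set()

    def add(name: str, role: str, **kw) -> None:
        if name in used:
            raise ValueError(f"duplicate planted gene name {name!r}")
        used.add(name)
        rows.append({"gene": name, "role": role, **kw})

    for i in range(params.n_mito_genes):
        name = MITO_GENE_NAMES[i] if i < len(MITO_GENE_NAMES) else f"mt-x{i}"
        add(name, "mito")

    lr_pairs = params.true_lr_pairs + params.decoy_lr_pairs
    lr_genes = {g for p in lr_pairs for g in (p.ligand, p.receptor)}

    types = list(KIDNEY_MARKERS)
    for k in range(params.n_clusters):
        cell_type = types[k % len(types)]
        canonical = KIDNEY_MARKERS[cell_type]
        names = list(canonical) + [
            f"Mk{k}G{j}" for j in range(len(canonical), params.marker_genes_per_cluster)
        ]
        for name in names[: params.marker_genes_per_cluster]:
            if name in lr_genes:
                continue  # shared symbol: planted below with its LR role
            add(name, "marker", cluster=k)

    for p in lr_pairs:
        kind = "true" if p in params.true_lr_pairs else "decoy"
        if p.ligand not in used:
            add(p.ligand, "ligand", pair_kind=kind)
        if p.receptor not in used:
            add(p.receptor, "receptor", pair_kind=kind)

    for mi, (size, latent_sd) in enumerate(params.planted_modules, start=1):
        for j in range(size):
            add(f"Mod{mi}G{j}", "module", module=f"M{mi}", latent_sd=latent_sd)

    n_bg = params.n_genes - len(rows)
    if n_bg < 0:
        raise ValueError(
            f"planted genes ({len(rows)}) exceed n_genes ({params.n_genes})"
        )
    for j in range(n_bg):
        add(f"Bg{j}", "background")
    return pd.DataFrame(rows)


def simulate_dataset(params: SimulationParams) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a two-condition count matrix and its planted truth.

    Deterministic per (params, seed): identical inputs give bit-identical
    matrices.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = _build_gene_table(params)
    gene_ids = genes["gene"].tolist()
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # baseline means per gene (shared by all clusters/conditions)
    base = rng.gamma(params.base_mean_shape, params.base_mean_scale, size=n_genes)
    base = np.maximum(base, 0.05)
    role = genes["role"].to_numpy()
    base[role == "mito"] = params.mito_gene_mean
    base[role == "marker"] = params.marker_base_mean
    base[role == "module"] = params.module_gene_mean
    # ligands/receptors stay near-silent outside their planted clusters
    base[np.isin(role, ["ligand", "receptor"])] = 0.1

    n_cond_cells = params.n_clusters * params.cells_per_cluster_per_condition
    cells: list[str] = []
    cell_cluster: list[int] = []
    cell_cond: list[str] = []
    for cond in ("control", "case"):
        for k in range(params.n_clusters):
            for j in range(params.cells_per_cluster_per_condition):
                cells.append(f"{cond}_c{k}_{j:04d}")
                cell_cluster.append(k)
                cell_cond.append(cond)
    # low-quality cells appended round-robin over clusters/conditions
    lq_kinds: list[str] = []
    kinds_available = ["low_features", "high_mito"]
    if n_genes > 2500:
        kinds_available.append("high_features")
    for j in range(params.n_low_quality_cells):
        cond = ("control", "case")[j % 2]
        k = j % max(params.n_clusters, 1)
        cells.append(f"{cond}_lq_{j:04d}")
        cell_cluster.append(k)
        cell_cond.append(cond)
        lq_kinds.append(kinds_available[j % len(kinds_available)])

    n_cells = len(cells)
    cluster_arr = np.array(cell_cluster)
    case_mask = np.array([c == "case" for c in cell_cond])

    # per-cell, per-gene log-mean adjustments
    log_mu = np.tile(np.log(base), (n_cells, 1))

    marker_boost = params.marker_log2_effect * np.log(2.0)
    for _, row in genes[genes["role"] == "marker"].iterrows():
        gi = gene_pos[row["gene"]]
        log_mu[cluster_arr == row["cluster"], gi] += marker_boost

    # planted ligand-receptor expression
    for p in params.true_lr_pairs + params.decoy_lr_pairs:
        li, ri = gene_pos[p.ligand], gene_pos[p.receptor]
        margin = params.detection_margin if p.target_fraction >= 0.5 else 1.0
        mu_case = detection_mean(p.target_fraction, params.nb_dispersion) * margin
        mu_ctrl = mu_case / p.ligand_fc
        sender = cluster_arr == p.sender_cluster
        log_mu[sender & case_mask, li] = np.log(mu_case)
        log_mu[sender & ~case_mask, li] = np.log(mu_ctrl)
        mu_rec = (
            detection_mean(params.receptor_target_fraction, params.nb_dispersion)
            * params.detection_margin
        )
        log_mu[cluster_arr == p.receiver_cluster, ri] = np.log(mu_rec)

    # planted modules: shared per-cell latent factor on member genes
    gene_to_module: dict[str, str] = {}
    for mi, (size, latent_sd) in enumerate(params.planted_modules, start=1):
        members = genes.index[genes["module"] == f"M{mi}"] if "module" in genes else []
        idx = [gene_pos[genes.loc[i, "gene"]] for i in members]
        z = rng.normal(0.0, 1.0, size=n_cells)
        if idx:
            # alternate loading signs and rescale so each cell's module total
            # is exactly flat: the latent then cannot leak into other genes
            # through library-size normalization, while the unsigned |cor|
            # network still sees one coherent block
            signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(len(idx))])
            mult = np.exp(np.outer(z * latent_sd, signs))  # cells x members
            base_mem = base[idx]
            flat = base_mem.sum() / (mult * base_mem).sum(axis=1)
            log_mu[:, idx] += np.log(mult * flat[:, None])
        for i in members:
            gene_to_module[genes.loc[i, "gene"]] = f"M{mi}"

    # library size variation (log-normal, mean params.library_size_mean)
    lib = params.library_size_mean * rng.lognormal(
        -0.5 * params.library_size_sigma**2, params.library_size_sigma, size=n_cells
    )
    log_mu += np.log(lib)[:, None]

    # negative-binomial draw: counts ~ Poisson(Gamma(r, mu/r))
    r = 1.0 / params.nb_dispersion
    mu = np.exp(log_mu)
    lam = rng.gamma(r, mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    # construct the QC violations
    qc_fail: set[str] = set()
    n_main = n_cond_cells * 2
    mito_idx = np.flatnonzero(role == "mito")
    for j, kind in enumerate(lq_kinds):
        ci = n_main + j
        qc_fail.add(cells[ci])
        if kind == "low_features":
            keep = rng.choice(n_genes, size=150, replace=False)
            mask = np.zeros(n_genes, dtype=bool)
            mask[keep] = True
            counts[ci, ~mask] = 0
        elif kind == "high_mito":
            non_mito_total = counts[ci].sum() - counts[ci, mito_idx].sum()
            per_gene = int(np.ceil(0.6 * max(non_mito_total, 1) / max(len(mito_idx), 1)))
            counts[ci, mito_idx] = per_gene
        elif kind == "high_features":
            on = rng.choice(n_genes, size=min(2600, n_genes), replace=False)
            counts[ci, on] = np.maximum(counts[ci, on], 1)

    is_mito = np.array([g.startswith("mt-") for g in gene_ids])
    sample = [f"{cond}_m{(i % 3) + 1}" for i, cond in enumerate(cell_cond)]
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=cells,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame(
            {"sample": sample, "condition": cell_cond}, index=pd.Index(cells)
        ),
        gene_meta=pd.DataFrame({"is_mito": is_mito}, index=pd.Index(gene_ids)),
    )
    truth = SyntheticTruth(
        cell_to_cluster=dict(zip(cells, (int(c) for c in cell_cluster))),
        gene_to_module=gene_to_module,
        true_interactions={p.key for p in params.true_lr_pairs},
        decoy_interactions={p.key for p in params.decoy_lr_pairs},
        qc_fail_cells=qc_fail,
    )
    return cm, truth


def lr_database(params: SimulationParams) -> list[LRPair]:
    """The merged LR database matching a simulation (true + decoy pairs)."""
    return [
        LRPair(p.ligand, p.receptor, "planted")
        for p in params.true_lr_pairs + params.decoy_lr_pairs
    ]


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """One row per planted element (clusters, modules, interactions, QC)."""
    rows: list[dict] = []
    clusters = sorted(set(truth.cell_to_cluster.values()))
    for k in clusters:
        n = sum(1 for v in truth.cell_to_cluster.values() if v == k)
        rows.append({"kind": "cluster", "name": str(k), "size": n})
    modules = sorted({m for m in truth.gene_to_module.values()})
    for m in modules:
        n = sum(1 for v in truth.gene_to_module.values() if v == m)
        rows.append({"kind": "module", "name": m, "size": n})
    for key in sorted(truth.true_interactions):
        rows.append({"kind": "true_interaction", "name": f"{key[2]}-{key[3]}",
                     "sender": key[0], "receiver": key[1]})
    for key in sorted(truth.decoy_interactions):
        rows.append({"kind": "decoy_interaction", "name": f"{key[2]}-{key[3]}",
                     "sender": key[0], "receiver": key[1]})
    for c in sorted(truth.qc_fail_cells):
        rows.append({"kind": "qc_fail_cell", "name": c})
    return pd.DataFrame(rows)
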