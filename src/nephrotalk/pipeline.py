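"""End-to-end orchestration: simulate/load -> QC -> cluster -> annotate ->
DE -> co-expression modules -> cross-talk, with a run manifest.

A run is fully specified by a RunConfig (YAML-serializable); identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cluster as cl
from . import crosstalk as ct
from . import de, qc, simulate, wgcna
from . import io as nio

log = logging.getLogger("nephrotalk")

STAGES = ["simulate", "qc", "cluster", "annotate", "deg", "modules", "crosstalk"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults mirror the module defaults."""

    out_dir: str = "run_out"
    seed: int = 0
    # input: either a counts directory (mtx triplet) or simulation
    counts_path: str | None = None
    simulate: bool = True
    # qc
    min_features: int = qc.DEFAULT_MIN_FEATURES
    max_features: int = qc.DEFAULT_MAX_FEATURES
    max_mito: float = qc.DEFAULT_MAX_MITO
    scale_factor: float = qc.DEFAULT_SCALE_FACTOR
    # clustering
    n_hvg: int = cl.DEFAULT_N_HVG
    n_components: int = cl.DEFAULT_N_COMPONENTS
    k_neighbors: int = cl.DEFAULT_K_NEIGHBORS
    resolution: float = cl.DEFAULT_RESOLUTION
    marker_table_path: str | None = None
    # modules
    pseudocell_size: int = wgcna.DEFAULT_GROUP_SIZE
    min_module_size: int = wgcna.DEFAULT_MIN_MODULE_SIZE
    cut_height: float = wgcna.DEFAULT_CUT_HEIGHT
    top_k_hubs: int = wgcna.DEFAULT_TOP_K_HUBS
    # crosstalk
    lr_db_paths: list[str] = field(default_factory=list)
    min_fraction: float = ct.DEFAULT_MIN_FRACTION
    min_fc: float = ct.DEFAULT_MIN_FC

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations; empty means the config is usable."""
    v: list[str] = []
    if config.min_features >= config.max_features:
        v.append(
            f"min_features ({config.min_features}) must be < "
            f"max_features ({config.max_features})"
        )
    if config.scale_factor <= 0:
        v.append(f"scale_factor must be positive, got {config.scale_factor}")
    if not (0.0 <= config.max_mito <= 1.0):
        v.append(f"max_mito must be in [0,1], got {config.max_mito}")
    if not (0.0 <= config.min_fraction <= 1.0):
        v.append(f"min_fraction must be in [0,1], got {config.min_fraction}")
    if config.min_fc <= 0:
        v.append(f"min_fc must be positive, got {config.min_fc}")
    if config.resolution <= 0:
        v.append(f"resolution must be positive, got {config.resolution}")
    if config.pseudocell_size < 1:
        v.append(f"pseudocell_size must be >= 1, got {config.pseudocell_size}")
    if not config.simulate:
        if config.counts_path is None:
            v.append("counts_path required when simulate is false")
        elif not Path(config.counts_path).exists():
            v.append(f"counts_path does not exist: {config.counts_path}")
    for p in config.lr_db_paths:
        if not Path(p).exists():
            v.append(f"lr database path does not exist: {p}")
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    t_all = time.time()

    def stage(name: str):
        log.info("stage %s ...", name)
        manifest["stages"][name] = {"started": True}
        return time.time()

    def done(name: str, t0: float, **info) -> None:
        el = time.time() - t0
        manifest["stages"][name].update(elapsed_s=round(el, 3), **info)
        log.info("stage %s done (%.1fs)", name, el)

    try:
        # ---- counts ----
        t0 = stage("simulate")
        if config.simulate:
            params = simulate.SimulationParams(seed=config.seed)
            counts, truth = simulate.simulate_dataset(params)
            nio.write_counts(counts, out / "counts")
            nio.write_json(
                {
                    "cell_to_cluster": truth.cell_to_cluster,
                    "gene_to_module": truth.gene_to_module,
                    "true_interactions": sorted(map(list, truth.true_interactions)),
                    "decoy_interactions": sorted(map(list, truth.decoy_interactions)),
                    "qc_fail_cells": sorted(truth.qc_fail_cells),
                },
                out / "truth.json",
            )
            _write_tsv(simulate.truth_report(truth), out / "truth_report.tsv")
            lr_db = simulate.lr_database(params)
            markers = simulate.default_marker_table(params.n_clusters)
            manifest["outputs"]["counts"] = str(out / "counts")
            manifest["outputs"]["truth"] = str(out / "truth.json")
        else:
            counts = nio.read_counts(config.counts_path)
            lr_db = nio.read_lr_database(config.lr_db_paths)
            markers = (
                cl.MarkerTable.from_frame(nio.read_marker_table(config.marker_table_path))
                if config.marker_table_path
                else simulate.default_marker_table()
            )
        if config.lr_db_paths:
            lr_db = nio.read_lr_database(config.lr_db_paths)
        done("simulate", t0, n_cells=counts.n_cells, n_genes=counts.n_genes)

        # ---- qc + normalize ----
        t0 = stage("qc")
        metrics = qc.compute_qc_metrics(counts)
        kept = qc.qc_filter(
            metrics, config.min_features, config.max_features, config.max_mito
        )
        _write_tsv(qc.qc_report(metrics, kept), out / "qc_report.tsv", index=True)
        norm = qc.normalize_log(counts, kept, config.scale_factor)
        manifest["outputs"]["qc_report"] = str(out / "qc_report.tsv")
        done("qc", t0, n_kept=len(kept), n_removed=counts.n_cells - len(kept))

        # ---- cluster ----
        t0 = stage("cluster")
        hvg = cl.select_hvg(norm, config.n_hvg)
        emb = cl.embed_pca(norm, hvg, config.n_components)
        labels = cl.cluster_cells(
            emb, norm.cell_ids, config.k_neighbors, config.resolution, config.seed
        )
        done("cluster", t0, n_clusters=len(labels.clusters))

        # ---- annotate ----
        t0 = stage("annotate")
        labels = cl.annotate_clusters(labels, norm, markers)
        _write_tsv(labels.to_frame(), out / "clusters.tsv", index=True)
        comp = cl.cluster_composition(labels, norm.cell_meta)
        _write_tsv(comp, out / "composition.tsv")
        manifest["outputs"]["clusters"] = str(out / "clusters.tsv")
        manifest["outputs"]["composition"] = str(out / "composition.tsv")
        done("annotate", t0, types={str(k): v for k, v in labels.cluster_to_type.items()})

        # ---- differential expression ----
        t0 = stage("deg")
        deg_frames = []
        skipped = []
        for k in labels.clusters:
            cond = norm.cell_meta.loc[labels.cells_of(k), "condition"]
            if (cond == "case").sum() < de.MIN_CELLS_PER_GROUP or (
                cond == "control"
            ).sum() < de.MIN_CELLS_PER_GROUP:
                skipped.append(int(k))
                continue
            deg_frames.append(de.deg_frame(de.rank_sum_deg(norm, labels, k)))
        degs = (
            pd.concat(deg_frames, ignore_index=True) if deg_frames else pd.DataFrame()
        )
        _write_tsv(degs, out / "deg.tsv")
        manifest["outputs"]["deg"] = str(out / "deg.tsv")
        done("deg", t0, n_records=len(degs), skipped_clusters=skipped)

        # ---- modules ----
        t0 = stage("modules")
        modules, expr = wgcna.run_module_analysis(
            norm,
            labels,
            group_size=config.pseudocell_size,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            seed=config.seed,
        )
        assign = pd.DataFrame(
            {"gene": list(modules.gene_to_module), "module": list(modules.gene_to_module.values())}
        )
        _write_tsv(assign, out / "modules.tsv")
        _write_tsv(modules.eigengenes, out / "eigengenes.tsv", index=True)
        _write_tsv(modules.module_trait_r, out / "module_trait_r.tsv", index=True)
        _write_tsv(modules.module_trait_p, out / "module_trait_p.tsv", index=True)
        hub_rows = []
        for m in modules.modules:
            hr = wgcna.hub_genes(
                expr, modules.eigengenes[m], modules.genes_of(m), config.top_k_hubs
            )
            hub_rows += [
                {"module": m, "rank": i + 1, "gene": g, "kME": v}
                for i, (g, v) in enumerate(hr.genes)
            ]
        _write_tsv(pd.DataFrame(hub_rows), out / "hub_genes.tsv")
        for name in ("modules", "eigengenes", "module_trait_r", "module_trait_p", "hub_genes"):
            manifest["outputs"][name] = str(out / f"{name}.tsv")
        done("modules", t0, beta=modules.beta, n_modules=len(modules.modules))

        # ---- crosstalk ----
        t0 = stage("crosstalk")
        kept_counts = counts.subset_cells(norm.cell_ids)
        edges = ct.infer_interactions(
            kept_counts, norm, labels, lr_db, config.min_fraction, config.min_fc
        )
        nio.write_interactions(edges, out / "interactions.tsv")
        pair_counts, ligand_counts = ct.interaction_summary(edges)
        _write_tsv(pair_counts, out / "interaction_pairs.tsv")
        _write_tsv(ligand_counts, out / "interaction_ligands.tsv")
        manifest["outputs"]["interactions"] = str(out / "interactions.tsv")
        manifest["outputs"]["interaction_pairs"] = str(out / "interaction_pairs.tsv")
        manifest["outputs"]["interaction_ligands"] = str(out / "interaction_ligands.tsv")
        done("crosstalk", t0, n_edges=len(edges))
    except Exception as exc:  # annotate the failing stage, then re-raise
        failing = next(
            (s for s in manifest["stages"] if "elapsed_s" not in manifest["stages"][s]),
            "unknown",
        )
        raise RuntimeError(f"pipeline failed at stage {failing!r}: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t_all, 3)
    manifest["checksums"] = {
        k: _sha256(Path(p))
        for k, p in manifest["outputs"].items()
        if Path(p).is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
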