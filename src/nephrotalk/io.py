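"""Readers and writers for the formats the pipeline touches.

Counts travel as a 10x-style MatrixMarket triplet (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``) with a cell-metadata TSV, or as a dense
delimited table.  Ligand-receptor databases are delimited files with
``ligand`` / ``receptor`` / ``source`` columns.  All readers validate and
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("control", "case")

MITO_PREFIX = "mt-"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class CountMatrix:
    """Raw integer cell-by-gene counts with cell and gene metadata.

    ``values`` is a CSR sparse matrix (cells x genes); iteration over
    nonzeros never densifies.  ``cell_meta`` carries ``sample`` and
    ``condition`` (one of :data:`CONDITIONS`); ``gene_meta`` carries the
    ``is_mito`` flag.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame  # index = cell_ids; columns: sample, condition
    gene_meta: pd.DataFrame  # index = gene_ids; columns: is_mito

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_ids, "gene id")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count encountered")
        if self.values.nnz and np.any(self.values.data != np.floor(self.values.data)):
            raise FormatError("non-integer count encountered")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise FormatError("cell_meta index does not match cell_ids")
        if list(self.gene_meta.index) != list(self.gene_ids):
            raise FormatError("gene_meta index does not match gene_ids")
        bad = set(self.cell_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        """Return the sub-matrix restricted to ``keep`` (order preserved)."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([pos[c] for c in keep], dtype=int)
        return CountMatrix(
            values=self.values[idx],
            cell_ids=list(keep),
            gene_ids=list(self.gene_ids),
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and (self.values != other.values).nnz == 0
            and self.cell_meta.equals(other.cell_meta)
            and self.gene_meta.equals(other.gene_meta)
        )


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor database entry; gene identity is the symbol string."""

    ligand: str
    receptor: str
    source: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


def infer_mito(gene_ids: Sequence[str]) -> np.ndarray:
    """Mouse-style mitochondrial flag from the ``mt-`` symbol prefix."""
    return np.array([g.startswith(MITO_PREFIX) for g in gene_ids], dtype=bool)


# ---------------------------------------------------------------------------
# counts


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write the 10x-style triplet plus cell-metadata TSV under ``path``."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    # MatrixMarket stores genes x cells, as 10x does
    scipy.io.mmwrite(str(d / "matrix.mtx"), counts.values.T.tocoo(), field="integer")
    feat = pd.DataFrame(
        {"gene_id": counts.gene_ids, "is_mito": counts.gene_meta["is_mito"].astype(int).values}
    )
    feat.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = counts.cell_meta.reset_index(names="cell_id")
    meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)


def read_counts(path: str | Path, layout: str = "mtx_triplet") -> CountMatrix:
    """Read a count matrix; ``layout`` is ``mtx_triplet`` or ``dense_table``.

    Round-trips with :func:`write_counts`.  Rejects dimension mismatches,
    duplicate ids and negative or fractional values, naming the offender.
    """
    p = Path(path)
    if layout == "mtx_triplet":
        return _read_mtx_triplet(p)
    if layout == "dense_table":
        return _read_dense_table(p)
    raise ValueError(f"unknown layout {layout!r}")


def _read_mtx_triplet(d: Path) -> CountMatrix:
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FormatError(f"missing {name} under {d}")
    mat = scipy.io.mmread(str(d / "matrix.mtx"))  # genes x cells
    feat = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    gene_ids = feat.iloc[:, 0].astype(str).tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)
    cell_ids = barcodes.iloc[:, 0].astype(str).tolist()
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(gene_ids)}, {len(cell_ids)})"
        )
    if feat.shape[1] >= 2:
        is_mito = feat.iloc[:, 1].astype(int).astype(bool).values
    else:
        is_mito = infer_mito(gene_ids)
    meta_path = d / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
        missing = {"cell_id", "sample", "condition"} - set(meta.columns)
        if missing:
            raise FormatError(f"cell_meta.tsv lacks columns {sorted(missing)}")
        meta = meta.set_index("cell_id")
        if set(meta.index) != set(cell_ids):
            raise FormatError("cell_meta.tsv cells do not match barcodes.tsv")
        meta = meta.loc[cell_ids]
    else:
        meta = pd.DataFrame(
            {"sample": "sample0", "condition": "control"}, index=pd.Index(cell_ids)
        )
    values = sp.csr_matrix(mat.T)
    return CountMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=meta,
        gene_meta=pd.DataFrame({"is_mito": is_mito}, index=pd.Index(gene_ids)),
    )


def _read_dense_table(path: Path) -> CountMatrix:
    """Delimited table: rows = cells, columns = genes, first column cell id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if np.any(vals < 0):
        bad = df.columns[np.any(vals < 0, axis=0)][0]
        raise FormatError(f"negative count in column {bad!r}")
    if np.any(vals != np.floor(vals)):
        bad = df.columns[np.any(vals != np.floor(vals), axis=0)][0]
        raise FormatError(f"non-integer count in column {bad!r}")
    cell_ids = [str(c) for c in df.index]
    gene_ids = [str(g) for g in df.columns]
    _check_unique(cell_ids, "cell id")
    _check_unique(gene_ids, "gene id")
    return CountMatrix(
        values=sp.csr_matrix(vals),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame(
            {"sample": "sample0", "condition": "control"}, index=pd.Index(cell_ids)
        ),
        gene_meta=pd.DataFrame(
            {"is_mito": infer_mito(gene_ids)}, index=pd.Index(gene_ids)
        ),
    )


# ---------------------------------------------------------------------------
# ligand-receptor database


def read_lr_database(paths: Sequence[str | Path]) -> list[LRPair]:
    """Union of delimited LR tables; duplicate (ligand, receptor) pairs are
    collapsed with their sources concatenated with ``;``."""
    merged: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        missing = {"ligand", "receptor"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        if "source" not in df.columns:
            df = df.assign(source=Path(path).name)
        for row in df.itertuples(index=False):
            key = (str(row.ligand), str(row.receptor))
            if key not in merged:
                merged[key] = []
                order.append(key)
            src = str(row.source)
            if src not in merged[key]:
                merged[key].append(src)
    return [
        LRPair(ligand=k[0], receptor=k[1], source=";".join(merged[k])) for k in order
    ]


def write_lr_database(pairs: Sequence[LRPair], path: str | Path) -> None:
    pd.DataFrame(
        [{"ligand": p.ligand, "receptor": p.receptor, "source": p.source} for p in pairs]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction edges

_EDGE_COLUMNS = [
    "sender_cluster",
    "receiver_cluster",
    "ligand",
    "receptor",
    "ligand_fraction_sender",
    "receptor_fraction_receiver",
    "ligand_fc",
    "condition_scope",
]


def write_interactions(edges, path: str | Path) -> None:
    """Write accepted interaction edges as a TSV with stable column order."""
    rows = [
        {
            "sender_cluster": e.sender_cluster,
            "receiver_cluster": e.receiver_cluster,
            "ligand": e.ligand,
            "receptor": e.receptor,
            "ligand_fraction_sender": e.ligand_fraction_sender,
            "receptor_fraction_receiver": e.receptor_fraction_receiver,
            "ligand_fc": e.ligand_fc,
            "condition_scope": e.condition_scope,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path):
    from .crosstalk import InteractionEdge

    df = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        InteractionEdge(
            ligand=str(r.ligand),
            receptor=str(r.receptor),
            sender_cluster=r.sender_cluster,
            receiver_cluster=r.receiver_cluster,
            ligand_fraction_sender=float(r.ligand_fraction_sender),
            receptor_fraction_receiver=float(r.receptor_fraction_receiver),
            ligand_fc=float(r.ligand_fc),
            condition_scope=str(r.condition_scope),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# marker tables and JSON helpers


def read_marker_table(path: str | Path) -> "pd.DataFrame":
    """Marker TSV with columns cell_type, markers (comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_type", "markers"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_marker_table(markers: dict[str, list[str]], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_type": list(markers), "markers": [",".join(v) for v in markers.values()]}
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
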