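"""Per-cell quality control and global-scaling log normalization.

A cell is summarized by the number of detected genes (raw count > 0), its
total counts, and the fraction of counts from mitochondrial genes.  The
filter keeps cells with min_features <= nFeature <= max_features and
mito_fraction <= max_mito; boundaries are inclusive on the keep side.
Kept counts are normalized to counts-per-scale_factor and natural-log
transformed: value = ln(1 + count / total * scale_factor), so that
sum(exp(value) - 1) == scale_factor for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

DEFAULT_MIN_FEATURES = 200
DEFAULT_MAX_FEATURES = 2500
DEFAULT_MAX_MITO = 0.30
DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class NormalizedMatrix:
    """Log-normalized expression for the kept cells.

    ``values`` is dense cells x genes (float64); sparsity of raw counts is
    preserved as exact zeros.  ``source`` records provenance.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    scale_factor: float
    source: CountMatrix | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def expm1(self) -> np.ndarray:
        """De-logged normalized expression (counts per scale_factor)."""
        return np.expm1(self.values)


def compute_qc_metrics(counts: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: n_features, total_counts, mito_fraction.

    Cells with zero total counts get mito_fraction 0 and ``zero_total`` True.
    """
    X = counts.values
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = counts.gene_meta["is_mito"].to_numpy()
    if mito_mask.any():
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_features": n_features.astype(int),
            "total_counts": total.astype(int),
            "mito_fraction": mito_fraction,
            "zero_total": total == 0,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def qc_filter(
    metrics: pd.DataFrame,
    min_features: int = DEFAULT_MIN_FEATURES,
    max_features: int = DEFAULT_MAX_FEATURES,
    max_mito: float = DEFAULT_MAX_MITO,
) -> list[str]:
    """Cell ids passing the threshold filter (boundaries kept inclusive)."""
    if min_features >= max_features:
        raise ValueError(
            f"min_features ({min_features}) must be < max_features ({max_features})"
        )
    keep = (
        (metrics["n_features"] >= min_features)
        & (metrics["n_features"] <= max_features)
        & (metrics["mito_fraction"] <= max_mito)
    )
    return metrics.index[keep].tolist()


def normalize_log(
    counts: CountMatrix,
    kept_cells: list[str] | None = None,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> NormalizedMatrix:
    """Counts-per-scale_factor, ln(1+x) transformed, over the kept cells."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    sub = counts if kept_cells is None else counts.subset_cells(kept_cells)
    X = sub.values.astype(np.float64).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = [sub.cell_ids[i] for i in np.flatnonzero(totals <= 0)][:5]
        raise ValueError(f"zero-total cells in kept set, e.g. {bad}")
    # scale each row, then log1p; operate on sparse data in place
    scaled = sp.csr_matrix(X, copy=True)
    row_factor = scale_factor / totals
    scaled.data *= np.repeat(row_factor, np.diff(scaled.indptr))
    values = np.asarray(scaled.todense())
    np.log1p(values, out=values)
    return NormalizedMatrix(
        values=values,
        cell_ids=list(sub.cell_ids),
        gene_ids=list(sub.gene_ids),
        cell_meta=sub.cell_meta.copy(),
        scale_factor=float(scale_factor),
        source=counts,
    )


def qc_report(metrics: pd.DataFrame, kept: list[str]) -> pd.DataFrame:
    """QC report table with a kept flag, ready for TSV export."""
    rep = metrics.copy()
    rep["kept"] = rep.index.isin(set(kept))
    return rep.drop(columns=["zero_total"])
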