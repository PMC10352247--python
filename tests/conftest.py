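import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nephrotalk import qc, simulate
from nephrotalk.io import CountMatrix


def make_counts(values, cell_ids=None, gene_ids=None, conditions=None):
    """Small dense-array CountMatrix builder for unit tests."""
    values = np.asarray(values)
    n_cells, n_genes = values.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    gene_ids = gene_ids or [f"g{j}" for j in range(n_genes)]
    conditions = conditions or ["control"] * n_cells
    return CountMatrix(
        values=sp.csr_matrix(values),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame(
            {"sample": "s0", "condition": conditions}, index=pd.Index(cell_ids)
        ),
        gene_meta=pd.DataFrame(
            {"is_mito": [g.startswith("mt-") for g in gene_ids]},
            index=pd.Index(gene_ids),
        ),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One default simulation shared by read-only tests (seed 3)."""
    params = simulate.SimulationParams(seed=3)
    counts, truth = simulate.simulate_dataset(params)
    metrics = qc.compute_qc_metrics(counts)
    kept = qc.qc_filter(metrics)
    norm = qc.normalize_log(counts, kept)
    return {
        "params": params,
        "counts": counts,
        "truth": truth,
        "metrics": metrics,
        "kept": kept,
        "norm": norm,
        "labels": truth.labeling(norm.cell_ids),
    }
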