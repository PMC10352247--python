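"""Ligand-receptor cross-talk inference between clusters.

An ordered (sender, receiver) cluster pair and a database ligand-receptor
pair become an interaction edge only if three criteria hold in the case
condition: both genes detected in at least 50% of their cluster's cells,
ligand case-vs-control fold change of at least 2 in the sender, and
nonzero mean expression of both genes.  Decoy pairs that break exactly one
criterion must be rejected.
"""

from nephrotalk import crosstalk as ct
from nephrotalk import qc, simulate

params = simulate.SimulationParams(seed=0)
counts, truth = simulate.simulate_dataset(params)
kept = qc.qc_filter(qc.compute_qc_metrics(counts))
norm = qc.normalize_log(counts, kept)
labels = truth.labeling(norm.cell_ids)

db = simulate.lr_database(params)  # 12 true + 20 decoy pairs
edges = ct.infer_interactions(counts.subset_cells(norm.cell_ids), norm, labels, db)
print(f"database pairs: {len(db)};  accepted edges: {len(edges)}")

keys = {e.key for e in edges}
print(f"true pairs recovered: {len(keys & truth.true_interactions)} / 12")
print(f"decoys admitted:      {len(keys & truth.decoy_interactions)} / 20")

print("\naccepted edges (sender -> receiver):")
for e in edges:
    print(
        f"  {e.sender_cluster} -> {e.receiver_cluster}: "
        f"{e.ligand}-{e.receptor}  "
        f"(lig frac {e.ligand_fraction_sender:.2f}, "
        f"rec frac {e.receptor_fraction_receiver:.2f}, "
        f"FC {e.ligand_fc:.1f})"
    )

pair_counts, ligand_counts = ct.interaction_summary(edges)
print("\nligands ranked by number of edges:")
print(ligand_counts.to_string(index=False))
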