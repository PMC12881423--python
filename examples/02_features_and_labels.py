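"""Derive core-omics node features from raw tables and curate labels.

Generates a small synthetic cohort (3 cancer types, 10 tumor/normal samples
each), computes the three per-type omics features — mutated fraction per kb,
log2 expression fold change, methylation beta difference — assembles the
pan-cancer feature matrix, and builds the positive/negative/unlabeled split.
"""

import numpy as np

from hyperdriver import (
    SyntheticSpec,
    assemble_core_features,
    assemble_labelset,
    build_negatives,
    build_positives,
    expression_features,
    generate_hypergraph,
    methylation_features,
    mutation_features,
    plant_drivers,
)

spec = SyntheticSpec(
    n_genes=300, n_pathways=40, edge_size_range=(5, 15),
    n_driver_pathways=6, n_cancer_types=3, samples_per_type=10, seed=5,
)
hg = generate_hypergraph(spec)
labels, _, omics = plant_drivers(hg, spec)

per_cancer = []
for ct, tables in omics.items():
    per_cancer.append(
        (ct, (mutation_features(tables), expression_features(tables),
              methylation_features(tables)))
    )
fm, standardizer = assemble_core_features(per_cancer, hg.genes, mode="pan")
print(f"feature matrix: {len(fm.genes)} genes x {fm.d} columns "
      f"(3 omics x {spec.n_cancer_types} types)")
print(f"columns: {fm.column_names[:6]} ...")

pos = sorted(labels.positives)[:3]
neg = sorted(labels.negatives)[:3]
col = fm.column_names.index("CT00_mut")
print(f"standardized mutation feature, planted drivers {pos}: "
      f"{np.round(fm.values[[fm.genes.index(g) for g in pos], col], 2)}")
print(f"standardized mutation feature, non-drivers {neg}: "
      f"{np.round(fm.values[[fm.genes.index(g) for g in neg], col], 2)}")
# Driver genes sit ~2 sd above background on mutation-derived columns.

positives = build_positives([labels.positives])
negative_universe = build_negatives(
    set(hg.genes), drivers=positives, pathway_flagged=set(), predicted_flagged=set()
)
print(f"{len(negative_universe)} genes eligible as negatives after excluding drivers")
ls = assemble_labelset(hg.genes, positives, labels.negatives)
print(f"labels: {len(ls.positives)} drivers, {len(ls.negatives)} non-drivers, "
      f"{len(ls.unlabeled)} unlabeled candidates")
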