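"""Build a gene–pathway hypergraph from a GMT file and inspect its structure.

Writes a tiny gene-set file, screens out cancer-named pathways (so topology
cannot leak label information), builds the incidence structure and prints
the normalized propagation operator used by the convolution layers.
"""

import tempfile
from pathlib import Path

import numpy as np

from hyperdriver import (
    build_hypergraph,
    degree_structure,
    filter_cancer_terms,
    parse_gmt,
    propagation_operator,
)

gmt = Path(tempfile.mkdtemp()) / "pathways.gmt"
gmt.write_text(
    "REACTOME_DNA_REPAIR\tdesc\tBRCA1\tBRCA2\tATM\n"
    "KEGG_MAPK_SIGNALING\tdesc\tKRAS\tBRAF\tMAPK1\tATM\n"
    "KEGG_PATHWAYS_IN_CANCER\tdesc\tTP53\tKRAS\tBRAF\n"
)

pc = parse_gmt(gmt)
pc, removed = filter_cancer_terms(pc)
print(f"pathways kept: {pc.ids()}  (removed {removed} cancer-named)")

hg = build_hypergraph(pc, min_edge_size=2)
ds = degree_structure(hg)
print(f"genes ({hg.n_genes}): {hg.genes}")
print(f"node degrees (pathways per gene):   {ds.node_degree}")
print(f"edge degrees (genes per pathway):   {ds.edge_degree}")

P = propagation_operator(hg)
print("propagation operator D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}:")
print(np.round(np.asarray(P.matrix.todense()), 3))
# Entries couple genes sharing a pathway; ATM bridges the two pathways, so
# its row has nonzero mass toward both gene groups.
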