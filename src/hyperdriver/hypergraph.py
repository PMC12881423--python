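"""Gene–pathway hypergraphs: GMT parsing, construction, weighting, propagation.

A hypergraph ``G = (V, E, W, X)`` models genes as nodes and biological
pathways as hyperedges, so that a single edge connects every gene that
participates in the same pathway.  The structure is carried by the binary
incidence matrix ``H`` (n genes x m pathways), with the diagonal node-degree
matrix ``D_v`` (pathways per gene) and hyperedge-degree matrix ``B`` (genes
per pathway).  Hyperedge weights ``W`` encode cancer relevance: a pathway
containing many known driver genes propagates more signal.

The normalized propagation operator

    P = D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}

is the message-passing kernel of the hypergraph convolution: each gene
averages features over the pathways it belongs to (the ``B^{-1} H^T`` pass),
then collects the weighted pathway summaries back (the ``H W`` pass), with
symmetric degree normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PathwayCollection",
    "Hypergraph",
    "DegreeStructure",
    "PropagationOperator",
    "GMTParseError",
    "DEFAULT_CANCER_TERMS",
    "parse_gmt",
    "filter_cancer_terms",
    "build_hypergraph",
    "degree_structure",
    "weight_hyperedges",
    "propagation_operator",
    "save_hypergraph",
    "load_hypergraph",
]

#: Substrings (lowercase) used to drop cancer-specific pathway names so the
#: topology itself does not leak label information.
DEFAULT_CANCER_TERMS = (
    "cancer",
    "tumor",
    "tumour",
    "carcinoma",
    "oncogen",
    "melanoma",
    "leukemia",
    "glioma",
)


class GMTParseError(ValueError):
    """Raised for malformed gene-set (GMT) input."""


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets (pathways).

    Gene symbols are uppercase-normalized on construction; pathway ids must
    be unique and every gene set non-empty.
    """

    pathways: list[tuple[str, frozenset[str]]]
    source_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        normalized = []
        for pid, genes in self.pathways:
            if pid in seen:
                raise ValueError(f"duplicate pathway id: {pid!r}")
            seen.add(pid)
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            normalized.append((pid, genes))
        self.pathways = normalized

    def __len__(self) -> int:
        return len(self.pathways)

    def ids(self) -> list[str]:
        return [pid for pid, _ in self.pathways]


@dataclass
class Hypergraph:
    """Gene–pathway incidence structure with hyperedge weights.

    ``genes`` is the canonical index for every feature matrix and label
    vector downstream; ``incidence`` is a sparse binary n x m matrix with
    ``incidence[i, j] = 1`` iff gene i belongs to pathway j.
    """

    genes: list[str]
    pathway_ids: list[str]
    incidence: sp.csr_matrix
    edge_weights: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = sp.csr_matrix(self.incidence, dtype=np.float64)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
        n, m = self.incidence.shape
        if len(self.genes) != n or len(self.pathway_ids) != m:
            raise ValueError("incidence shape does not match gene/pathway lists")
        if self.edge_weights.shape != (m,):
            raise ValueError("edge_weights must have one entry per hyperedge")
        data = self.incidence.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("incidence entries must be binary")
        if m and (self.incidence.getnnz(axis=0) == 0).any():
            raise ValueError("every hyperedge must contain at least one gene")
        if np.any(self.edge_weights < 0):
            raise ValueError("edge_weights must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class DegreeStructure:
    """Diagonals of the node-degree (D_v) and hyperedge-degree (B) matrices."""

    node_degree: np.ndarray
    edge_degree: np.ndarray

    def __post_init__(self) -> None:
        self.node_degree = np.asarray(self.node_degree, dtype=np.int64)
        self.edge_degree = np.asarray(self.edge_degree, dtype=np.int64)
        if (self.node_degree < 0).any():
            raise ValueError("node degrees must be nonnegative")
        if (self.edge_degree <= 0).any():
            raise ValueError("edge degrees must be positive")
        if self.node_degree.sum() != self.edge_degree.sum():
            raise ValueError("incidence mass mismatch between node and edge degrees")


@dataclass
class PropagationOperator:
    """Symmetric n x n sparse operator D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}."""

    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.float64)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("propagation operator must be square")

    def __matmul__(self, other: np.ndarray) -> np.ndarray:
        return self.matrix @ other

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def parse_gmt(path: str | Path) -> PathwayCollection:
    """Parse a tab-separated gene-set file (name, description, genes...).

    Duplicate symbols within a line are deduplicated; the description field
    is discarded.  Lines with fewer than 3 fields raise
    :class:`GMTParseError` naming the offending line number.
    """
    path = Path(path)
    pathways: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid = fields[0].strip()
            if pid in seen:
                raise GMTParseError(f"{path.name}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise GMTParseError(f"{path.name}:{lineno}: pathway {pid!r} has no genes")
            pathways.append((pid, genes))
    return PathwayCollection(pathways=pathways)


def filter_cancer_terms(
    pc: PathwayCollection,
    blacklist: list[str] | tuple[str, ...] = DEFAULT_CANCER_TERMS,
) -> tuple[PathwayCollection, int]:
    """Drop pathways whose id contains any blacklisted substring (case-insensitive).

    Returns the surviving collection (order preserved) and the removed count.
    """
    if not blacklist:
        raise ValueError("blacklist must be non-empty")
    terms = [t.lower() for t in blacklist]
    kept = [
        (pid, genes)
        for pid, genes in pc.pathways
        if not any(t in pid.lower() for t in terms)
    ]
    removed = len(pc.pathways) - len(kept)
    return PathwayCollection(pathways=kept, source_tags=dict(pc.source_tags)), removed


def build_hypergraph(
    pc: PathwayCollection,
    gene_universe: set[str] | None = None,
    min_edge_size: int = 2,
) -> Hypergraph:
    """Build the gene–pathway hypergraph from a pathway collection.

    Pathway members are optionally intersected with ``gene_universe`` (e.g.
    genes that have omics measurements); hyperedges smaller than
    ``min_edge_size`` after intersection are dropped (singletons contribute
    only self-loops).  Gene order is the sorted union of surviving members;
    edge weights are initialized to one.
    """
    if min_edge_size < 1:
        raise ValueError("min_edge_size must be >= 1")
    if gene_universe is not None:
        gene_universe = {g.upper() for g in gene_universe}

    surviving: list[tuple[str, frozenset[str]]] = []
    for pid, genes in pc.pathways:
        if gene_universe is not None:
            genes = genes & gene_universe
        if len(genes) >= min_edge_size:
            surviving.append((pid, frozenset(genes)))
    if not surviving:
        raise ValueError("no hyperedges survive filtering")

    gene_list = sorted(set().union(*(genes for _, genes in surviving)))
    gidx = {g: i for i, g in enumerate(gene_list)}

    rows, cols = [], []
    for j, (_, genes) in enumerate(surviving):
        for g in genes:
            rows.append(gidx[g])
            cols.append(j)
    H = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(gene_list), len(surviving)),
    )
    return Hypergraph(
        genes=gene_list,
        pathway_ids=[pid for pid, _ in surviving],
        incidence=H,
        edge_weights=np.ones(len(surviving)),
    )


def hypergraph_from_memberships(
    genes: list[str],
    pathway_ids: list[str],
    memberships: list[list[int]],
) -> Hypergraph:
    """Construct a hypergraph over an explicit gene list (isolated genes allowed).

    ``memberships[j]`` lists the gene indices of hyperedge j.
    """
    rows, cols = [], []
    for j, members in enumerate(memberships):
        for i in set(members):
            rows.append(i)
            cols.append(j)
    H = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(genes), len(pathway_ids)),
    )
    return Hypergraph(
        genes=list(genes),
        pathway_ids=list(pathway_ids),
        incidence=H,
        edge_weights=np.ones(len(pathway_ids)),
    )


def degree_structure(hg: Hypergraph) -> DegreeStructure:
    """Node degrees (pathways per gene) and edge degrees (genes per pathway)."""
    node_degree = np.asarray(hg.incidence.sum(axis=1)).ravel().astype(np.int64)
    edge_degree = np.asarray(hg.incidence.sum(axis=0)).ravel().astype(np.int64)
    return DegreeStructure(node_degree=node_degree, edge_degree=edge_degree)


def weight_hyperedges(
    hg: Hypergraph,
    training_positives: set[str],
    smoothing: float = 1.0,
) -> Hypergraph:
    """Weight each hyperedge by the known driver genes it contains.

    ``edge_weights[j] = smoothing + |e_j ∩ training_positives|``.  The
    additive smoothing (default 1) keeps driver-free pathways propagating at
    baseline and reduces to the unweighted graph when no labels are known.

    Leakage contract: callers must pass positives from *training* folds only;
    validation/test labels never influence the weights.  Returns a new
    hypergraph; the input is not modified.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    positives = {g.upper() for g in training_positives}
    pos_idx = [i for i, g in enumerate(hg.genes) if g in positives]
    indicator = np.zeros(hg.n_genes)
    indicator[pos_idx] = 1.0
    counts = np.asarray(indicator @ hg.incidence).ravel()
    return Hypergraph(
        genes=list(hg.genes),
        pathway_ids=list(hg.pathway_ids),
        incidence=hg.incidence.copy(),
        edge_weights=smoothing + counts,
    )


def propagation_operator(hg: Hypergraph) -> PropagationOperator:
    """The normalized propagation kernel D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}.

    Zero-degree genes (in the universe but in no pathway) get zero rows and
    columns (pseudo-inverse convention for D_v); they are rescued downstream
    by the readout's skip connection to the raw features.

    The operator is assembled as ``M M^T`` with
    ``M = D_v^{-1/2} H (W B^{-1})^{1/2}``, which guarantees exact symmetry.
    """
    deg = degree_structure(hg)
    inv_sqrt_dv = np.zeros(hg.n_genes)
    nz = deg.node_degree > 0
    inv_sqrt_dv[nz] = 1.0 / np.sqrt(deg.node_degree[nz])
    edge_scale = np.sqrt(hg.edge_weights / deg.edge_degree)

    M = sp.diags(inv_sqrt_dv) @ hg.incidence @ sp.diags(edge_scale)
    P = M @ M.T
    P = ((P + P.T) * 0.5).tocsr()
    return PropagationOperator(matrix=P)


def save_hypergraph(hg: Hypergraph, out_dir: str | Path) -> None:
    """Serialize to a directory of plain-text artifacts.

    Layout: genes.txt, pathways.txt, incidence.tsv (gene_index, pathway_index
    triplets), weights.tsv and header.json with n, m, nnz.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genes.txt").write_text("\n".join(hg.genes) + "\n")
    (out / "pathways.txt").write_text("\n".join(hg.pathway_ids) + "\n")
    coo = hg.incidence.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with (out / "incidence.tsv").open("w") as fh:
        fh.write("gene_index\tpathway_index\n")
        for i, j in zip(coo.row[order], coo.col[order]):
            fh.write(f"{i}\t{j}\n")
    with (out / "weights.tsv").open("w") as fh:
        fh.write("pathway_index\tweight\n")
        for j, w in enumerate(hg.edge_weights):
            fh.write(f"{j}\t{w:.17g}\n")
    header = {"n": hg.n_genes, "m": hg.n_edges, "nnz": int(hg.incidence.nnz)}
    (out / "header.json").write_text(json.dumps(header, indent=2) + "\n")


def load_hypergraph(in_dir: str | Path) -> Hypergraph:
    """Load a hypergraph serialized by :func:`save_hypergraph`."""
    src = Path(in_dir)
    genes = src.joinpath("genes.txt").read_text().splitlines()
    pathway_ids = src.joinpath("pathways.txt").read_text().splitlines()
    header = json.loads(src.joinpath("header.json").read_text())
    rows, cols = [], []
    with src.joinpath("incidence.tsv").open() as fh:
        next(fh)
        for line in fh:
            i, j = line.split("\t")
            rows.append(int(i))
            cols.append(int(j))
    weights = np.ones(len(pathway_ids))
    with src.joinpath("weights.tsv").open() as fh:
        next(fh)
        for line in fh:
            j, w = line.split("\t")
            weights[int(j)] = float(w)
    H = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(header["n"], header["m"]),
    )
    return Hypergraph(
        genes=genes, pathway_ids=pathway_ids, incidence=H, edge_weights=weights
    )
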