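"""Curation of driver / non-driver / unlabeled gene sets.

Positives come from unions of curated driver catalogs (CGC, NCG,
literature-mined lists); negatives are built conservatively by excluding,
from the gene universe, (1) any known driver, (2) genes in cancer-related
pathways, and (3) genes flagged cancer-associated by prior computational
models.  Everything else stays unlabeled — those genes still participate in
representation learning and are the candidate pool for discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "build_positives",
    "build_negatives",
    "assemble_labelset",
    "eligible_cancer_types",
    "read_gene_list",
    "save_labelset",
    "load_labelset",
]


def _norm(genes) -> set[str]:
    return {str(g).upper() for g in genes}


@dataclass
class LabelSet:
    """Disjoint partition of (a subset of) hypergraph genes into classes."""

    positives: set[str]
    negatives: set[str]
    unlabeled: set[str]
    task_tag: str = "pan"

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if (self.positives | self.negatives) & self.unlabeled:
            raise ValueError("unlabeled genes overlap labeled genes")

    @property
    def n_labeled(self) -> int:
        return len(self.positives) + len(self.negatives)


def build_positives(sources: list[set[str] | list[str]]) -> set[str]:
    """Union of driver catalogs, symbol-normalized."""
    if not sources:
        raise ValueError("need at least one positive source")
    out: set[str] = set()
    for src in sources:
        out |= _norm(src)
    if not out:
        raise ValueError("union of positive sources is empty")
    return out


def build_negatives(
    universe: set[str],
    drivers: set[str],
    pathway_flagged: set[str],
    predicted_flagged: set[str],
) -> set[str]:
    """Three-step conservative exclusion from the universe.

    Removes known drivers, then genes in cancer-related pathways, then genes
    predicted cancer-associated by earlier models; logs per-step counts.
    Order-independent: equals universe minus the union of exclusions.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    result = _norm(universe)
    for step, excl in (
        ("drivers", drivers),
        ("pathway_flagged", pathway_flagged),
        ("predicted_flagged", predicted_flagged),
    ):
        before = len(result)
        result -= _norm(excl)
        logger.info("build_negatives: step %s removed %d genes", step, before - len(result))
    if not result:
        raise ValueError("no genes remain after negative-set exclusion")
    return result


def assemble_labelset(hg_genes: list[str], positives, negatives, task_tag: str = "pan") -> LabelSet:
    """Restrict labels to hypergraph genes; the rest become unlabeled.

    Genes claimed by both classes raise an error listing the offenders
    (conflicts must be resolved explicitly by the caller, never silently).
    Labeled genes absent from the hypergraph are dropped with a logged count.
    """
    gene_set = _norm(hg_genes)
    pos, neg = _norm(positives), _norm(negatives)
    clash = pos & neg
    if clash:
        raise ValueError(f"genes labeled both positive and negative: {sorted(clash)}")
    dropped = len(pos - gene_set) + len(neg - gene_set)
    if dropped:
        logger.info("assemble_labelset: %d labeled genes not in hypergraph dropped", dropped)
    pos &= gene_set
    neg &= gene_set
    return LabelSet(
        positives=pos,
        negatives=neg,
        unlabeled=gene_set - pos - neg,
        task_tag=task_tag,
    )


def eligible_cancer_types(
    per_type_driver_counts: dict[str, int], min_drivers: int = 15
) -> list[str]:
    """Cancer types with at least ``min_drivers`` known drivers, sorted.

    Types with fewer drivers are excluded — too little supervision for
    reliable per-type training; the threshold is inclusive.
    """
    return sorted(t for t, c in per_type_driver_counts.items() if c >= min_drivers)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.upper())
    return out


def save_labelset(ls: LabelSet, path: str | Path) -> None:
    """TSV with label codes 1 (driver), 0 (non-driver), -1 (unlabeled)."""
    with Path(path).open("w") as fh:
        fh.write("gene\tlabel\n")
        for g in sorted(ls.positives):
            fh.write(f"{g}\t1\n")
        for g in sorted(ls.negatives):
            fh.write(f"{g}\t0\n")
        for g in sorted(ls.unlabeled):
            fh.write(f"{g}\t-1\n")


def load_labelset(path: str | Path, task_tag: str = "pan") -> LabelSet:
    pos, neg, unl = set(), set(), set()
    with Path(path).open() as fh:
        next(fh)
        for line in fh:
            gene, label = line.strip().split("\t")
            {"1": pos, "0": neg, "-1": unl}[label].add(gene.upper())
    return LabelSet(positives=pos, negatives=neg, unlabeled=unl, task_tag=task_tag)
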