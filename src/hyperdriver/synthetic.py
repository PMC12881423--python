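"""Synthetic benchmarks with planted driver structure.

The generator emulates the real study design at desk scale: a random
gene–pathway hypergraph, a handful of "driver pathways" whose members are
enriched for positives (drivers of the same cancer cluster in shared
pathways), Gaussian core-omics-style features with a mean shift on the
mutation columns of positives, and raw omics tables (mutation counts, FPKM,
beta values) whose derived features carry the same planted separation, so
the feature-engineering pipeline can be exercised end to end.

Default condition: 2,000 genes, 200 pathways of 5–50 genes, 20 driver
pathways with half their members positive, effect size 2 standard
deviations, 16 cancer types with 20 tumor/normal samples each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, OmicsTables
from .hypergraph import Hypergraph, hypergraph_from_memberships, save_hypergraph
from .labels import LabelSet, save_labelset

__all__ = ["SyntheticSpec", "generate_hypergraph", "plant_drivers", "write_synthetic_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-driver benchmark."""

    n_genes: int = 2000
    n_pathways: int = 200
    edge_size_range: tuple[int, int] = (5, 50)
    n_driver_pathways: int = 20
    driver_fraction_within: float = 0.5
    effect_size: float = 2.0  # mean shift on mutation columns, in noise-sd units
    noise_sd: float = 1.0
    n_cancer_types: int = 16
    samples_per_type: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_driver_pathways > self.n_pathways:
            raise ValueError("n_driver_pathways cannot exceed n_pathways")
        for name in ("n_genes", "n_pathways", "n_cancer_types", "samples_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.edge_size_range
        if lo < 1 or hi < lo:
            raise ValueError("edge_size_range must satisfy 1 <= min <= max")

    def cancer_types(self) -> list[str]:
        return [f"CT{i:02d}" for i in range(self.n_cancer_types)]


def generate_hypergraph(spec: SyntheticSpec) -> Hypergraph:
    """Random hypergraph: each pathway draws a uniform size, then members
    uniformly without replacement.  Genes joining no pathway stay isolated
    (zero node degree), exercising the pseudo-inverse normalization path.
    """
    lo, hi = spec.edge_size_range
    if hi > spec.n_genes:
        raise ValueError("maximum edge size exceeds number of genes")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    memberships = []
    for _ in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        memberships.append(rng.choice(spec.n_genes, size=size, replace=False).tolist())
    pathway_ids = [f"PW{j:04d}" for j in range(spec.n_pathways)]
    return hypergraph_from_memberships(genes, pathway_ids, memberships)


def plant_drivers(
    hg: Hypergraph, spec: SyntheticSpec
) -> tuple[LabelSet, FeatureMatrix, dict[str, OmicsTables]]:
    """Plant driver labels, matching features, and raw omics tables.

    Labels: ``n_driver_pathways`` hyperedges are chosen; within each, a
    ``driver_fraction_within`` share of members become positives.  An
    equal-sized negative set is sampled from genes belonging to *no* driver
    pathway, so signal lives in both topology and features; the rest are
    unlabeled.

    Features: d = 3 x n_cancer_types Gaussian columns (noise_sd scale) with
    a +effect_size * noise_sd shift on each cancer type's mutation column
    for positives.

    Omics: per cancer type, Bernoulli mutation counts (positives mutate more
    often), gamma-distributed FPKM with an expression fold change for
    positives, and beta-valued methylation with a tumor shift for positives
    — all passing the feature-engineering preconditions.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n, m = hg.n_genes, hg.n_edges

    driver_edges = rng.choice(m, size=spec.n_driver_pathways, replace=False)
    H = hg.incidence.tocsc()
    positives: set[int] = set()
    driver_pathway_genes: set[int] = set()
    for j in driver_edges:
        members = H.indices[H.indptr[j]:H.indptr[j + 1]]
        driver_pathway_genes.update(int(i) for i in members)
        k = max(1, int(round(spec.driver_fraction_within * len(members))))
        chosen = rng.choice(members, size=k, replace=False)
        positives.update(int(i) for i in chosen)

    non_driver_pool = np.array(sorted(set(range(n)) - driver_pathway_genes))
    if len(non_driver_pool) < len(positives):
        raise ValueError(
            "not enough genes outside driver pathways to sample negatives"
        )
    negatives = set(
        int(i) for i in rng.choice(non_driver_pool, size=len(positives), replace=False)
    )

    pos_genes = {hg.genes[i] for i in positives}
    neg_genes = {hg.genes[i] for i in negatives}
    labels = LabelSet(
        positives=pos_genes,
        negatives=neg_genes,
        unlabeled=set(hg.genes) - pos_genes - neg_genes,
        task_tag="synthetic-pan",
    )

    types = spec.cancer_types()
    cols = [f"{ct}_{sfx}" for ct in types for sfx in ("mut", "expr", "meth")]
    values = spec.noise_sd * rng.standard_normal((n, len(cols)))
    pos_idx = np.array(sorted(positives))
    shift = spec.effect_size * spec.noise_sd
    for c, name in enumerate(cols):
        if name.endswith("_mut"):
            values[pos_idx, c] += shift
    fm = FeatureMatrix(genes=list(hg.genes), values=values, column_names=cols,
                       family_tag="core")

    is_pos = np.zeros(n, dtype=bool)
    is_pos[pos_idx] = True
    omics = {
        ct: _omics_for_type(hg.genes, is_pos, spec, rng, ct) for ct in types
    }
    return labels, fm, omics


def _omics_for_type(
    genes: list[str],
    is_pos: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    cancer_type: str,
) -> OmicsTables:
    n = len(genes)
    s = spec.samples_per_type

    # mutation: positives mutated in ~35% of samples vs 5% background
    p_mut = np.where(is_pos, 0.35, 0.05)
    mutation = rng.binomial(1, p_mut, size=(s, n))
    lengths = rng.integers(1000, 3001, size=n)

    # expression: tumor/normal FPKM around 5, ~2-fold up-regulation in positives
    base = 5.0 * np.ones(n)
    tumor_mean = base * np.where(is_pos, 2.0, 1.0)
    normal_expr = rng.gamma(shape=4.0, scale=base / 4.0, size=(s, n))
    tumor_expr = rng.gamma(shape=4.0, scale=tumor_mean / 4.0, size=(s, n))

    # methylation: betas near 0.5; tumor gains ~0.2 in positives
    normal_beta = np.clip(rng.normal(0.5, 0.05, size=(s, n)), 0.0, 1.0)
    tum_center = np.where(is_pos, 0.7, 0.5)
    tumor_beta = np.clip(rng.normal(tum_center, 0.05, size=(s, n)), 0.0, 1.0)

    samples = [f"{cancer_type}_S{i:03d}" for i in range(s)]
    return OmicsTables(
        mutation_counts=pd.DataFrame(mutation, index=samples, columns=genes),
        gene_lengths=pd.Series(lengths, index=genes),
        tumor_expr=pd.DataFrame(tumor_expr, index=samples, columns=genes),
        normal_expr=pd.DataFrame(normal_expr, index=samples, columns=genes),
        tumor_beta=pd.DataFrame(tumor_beta, index=samples, columns=genes),
        normal_beta=pd.DataFrame(normal_beta, index=samples, columns=genes),
        cancer_type=cancer_type,
    )


def write_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset in the formats the real pipeline reads.

    Produces pathways.gmt, a serialized hypergraph directory, labels.tsv,
    features.tsv and one omics directory per cancer type with
    mutation_counts / tumor_expr / normal_expr / tumor_beta / normal_beta /
    gene_lengths TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hg = generate_hypergraph(spec)
    labels, fm, omics = plant_drivers(hg, spec)

    H = hg.incidence.tocsc()
    with (out / "pathways.gmt").open("w") as fh:
        for j, pid in enumerate(hg.pathway_ids):
            members = [hg.genes[i] for i in H.indices[H.indptr[j]:H.indptr[j + 1]]]
            fh.write("\t".join([pid, "synthetic"] + sorted(members)) + "\n")

    save_hypergraph(hg, out / "graph")
    save_labelset(labels, out / "labels.tsv")
    fm_df = fm.to_frame()
    fm_df.index.name = "gene"
    fm_df.to_csv(out / "features.tsv", sep="\t")

    omics_root = out / "omics"
    for ct, tables in omics.items():
        d = omics_root / ct
        d.mkdir(parents=True, exist_ok=True)
        tables.mutation_counts.to_csv(d / "mutation_counts.tsv", sep="\t")
        tables.tumor_expr.to_csv(d / "tumor_expr.tsv", sep="\t")
        tables.normal_expr.to_csv(d / "normal_expr.tsv", sep="\t")
        tables.tumor_beta.to_csv(d / "tumor_beta.tsv", sep="\t")
        tables.normal_beta.to_csv(d / "normal_beta.tsv", sep="\t")
        tables.gene_lengths.rename("length_bp").to_csv(d / "gene_lengths.tsv", sep="\t")

    return {
        "gmt": out / "pathways.gmt",
        "graph": out / "graph",
        "labels": out / "labels.tsv",
        "features": out / "features.tsv",
        "omics": omics_root,
    }
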