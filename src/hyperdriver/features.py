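"""Node feature families: incidence-based, core omics, and comprehensive.

Three families initialize gene representations:

* *incidence-based* — the gene's binary pathway-membership vector, pure
  topology with no molecular annotation;
* *core omics* — per cancer type: non-silent mutation frequency normalized
  by gene length (hypermutated samples excluded), log2 tumor/normal
  expression fold change on FPKM, and the tumor-minus-normal difference in
  mean methylation beta value;
* *comprehensive* — a curated table of per-gene functional annotations
  (pathogenicity scores, conservation, histone marks, ...), 44 numeric
  columns in the reference setting.

Standardization statistics are always fit on training genes only and reused
on validation/test genes via the returned :class:`Standardizer`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph

__all__ = [
    "OmicsTables",
    "FeatureMatrix",
    "Standardizer",
    "mutation_features",
    "expression_features",
    "methylation_features",
    "assemble_core_features",
    "incidence_features",
    "load_comprehensive_features",
    "combine_features",
    "save_feature_matrix",
    "load_feature_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class OmicsTables:
    """Per-cancer-type omics tables (samples x genes, gene symbols as columns).

    ``mutation_counts`` holds non-silent mutation counts per sample and gene;
    ``tumor_expr``/``normal_expr`` are FPKM matrices; ``tumor_beta``/
    ``normal_beta`` are methylation beta values already aggregated to gene
    level (mean over gene-associated probes).
    """

    mutation_counts: pd.DataFrame
    gene_lengths: pd.Series
    tumor_expr: pd.DataFrame
    normal_expr: pd.DataFrame
    tumor_beta: pd.DataFrame
    normal_beta: pd.DataFrame
    cancer_type: str = "PAN"

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        for name in ("tumor_expr", "normal_expr"):
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"{name} must be nonnegative (FPKM)")
        for name in ("tumor_beta", "normal_beta"):
            b = getattr(self, name).to_numpy()
            if b.size and ((b < 0) | (b > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")
        if (self.mutation_counts.to_numpy() < 0).any():
            raise ValueError("mutation counts must be nonnegative")


@dataclass
class FeatureMatrix:
    """An n x d feature block aligned to a hypergraph's gene order."""

    genes: list[str]
    values: np.ndarray
    column_names: list[str]
    family_tag: str = "core"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.genes) != n:
            raise ValueError("gene list length does not match row count")
        if len(self.column_names) != d:
            raise ValueError("column_names length does not match column count")
        if len(set(self.column_names)) != d:
            raise ValueError("column names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN after imputation")

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.column_names)


@dataclass
class Standardizer:
    """Per-column z-scoring with statistics frozen on training genes."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    std: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def fit(self, values: np.ndarray, train_rows: np.ndarray | None = None) -> "Standardizer":
        sub = values if train_rows is None else values[train_rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            self.mean = np.nanmean(sub, axis=0)
            self.std = np.nanstd(sub, axis=0)
        self.mean = np.where(np.isnan(self.mean), 0.0, self.mean)
        self.std = np.where((self.std == 0) | np.isnan(self.std), 1.0, self.std)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std


def mutation_features(
    t: OmicsTables, ultra_mut_threshold: int = 1000, per_sample_total: bool = False
) -> pd.Series:
    """Fraction of samples carrying a non-silent mutation, per kilobase.

    Samples whose total non-silent mutation count exceeds
    ``ultra_mut_threshold`` (hypermutators) are excluded before computing the
    per-gene mutated fraction, which is then divided by gene length in kb.
    With ``per_sample_total=True`` the numerator is the total mutation count
    across retained samples instead of the mutated-sample fraction.
    """
    totals = t.mutation_counts.sum(axis=1)
    retained = t.mutation_counts.loc[totals <= ultra_mut_threshold]
    if retained.shape[0] == 0:
        raise ValueError("no samples retained after ultra-mutation filtering")
    if per_sample_total:
        numer = retained.sum(axis=0).astype(float)
    else:
        numer = (retained >= 1).mean(axis=0)
    length_kb = t.gene_lengths.reindex(retained.columns) / 1000.0
    return (numer / length_kb).astype(float)


def expression_features(
    t: OmicsTables,
    pseudocount: float = 1e-3,
    pairing: dict[str, str] | None = None,
) -> pd.Series:
    """log2 fold change of mean tumor vs mean normal FPKM.

    With a ``pairing`` map (tumor sample -> matched normal sample) the
    feature is the mean of per-pair log2 ratios instead of the ratio of
    means.  Genes present in only one condition come back NaN; downstream
    imputation maps them to 0 with a logged count.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if t.tumor_expr.shape[0] == 0 or t.normal_expr.shape[0] == 0:
        raise ValueError("need at least one tumor and one normal sample")
    if pairing is not None:
        ratios = []
        for tum, norm in pairing.items():
            ratios.append(
                np.log2(
                    (t.tumor_expr.loc[tum] + pseudocount)
                    / (t.normal_expr.loc[norm] + pseudocount)
                )
            )
        return pd.concat(ratios, axis=1).mean(axis=1)
    genes = t.tumor_expr.columns.union(t.normal_expr.columns)
    tum_mean = t.tumor_expr.mean(axis=0).reindex(genes)
    norm_mean = t.normal_expr.mean(axis=0).reindex(genes)
    feat = np.log2((tum_mean + pseudocount) / (norm_mean + pseudocount))
    n_missing = int(feat.isna().sum())
    if n_missing:
        logger.info("expression_features: %d genes missing in one condition", n_missing)
    return feat


def methylation_features(t: OmicsTables) -> pd.Series:
    """Mean tumor beta minus mean normal beta, per gene (range [-1, 1])."""
    return t.tumor_beta.mean(axis=0) - t.normal_beta.mean(axis=0)


def assemble_core_features(
    per_cancer: list[tuple[str, tuple[pd.Series, pd.Series, pd.Series]]],
    genes: list[str],
    mode: str = "pan",
    train_rows: np.ndarray | None = None,
) -> tuple[FeatureMatrix, Standardizer]:
    """Concatenate per-cancer-type (mutation, expression, methylation) vectors.

    Pan mode stacks all cancer types (sorted by name) into a
    ``3 * n_types``-dimensional vector per gene — 48 columns in the
    16-cancer-type reference setting; specific mode takes exactly one type
    (d = 3).  Within each type the column order is mutation, expression,
    methylation.  Genes absent from a table are NaN before standardization
    and imputed to 0 afterwards (absence ~ population mean).  The returned
    :class:`Standardizer` was fit on ``train_rows`` (all rows by default).
    """
    if mode not in {"pan", "specific"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "specific" and len(per_cancer) != 1:
        raise ValueError("specific mode requires exactly one cancer type")
    if not per_cancer:
        raise ValueError("need at least one cancer type")
    for ct, vecs in per_cancer:
        if len(vecs) != 3:
            raise ValueError(
                f"cancer type {ct!r} must contribute exactly 3 vectors "
                f"(mutation, expression, methylation), got {len(vecs)}"
            )

    ordered = sorted(per_cancer, key=lambda item: item[0])
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for ct, (mut, expr, meth) in ordered:
        for suffix, vec in (("mut", mut), ("expr", expr), ("meth", meth)):
            cols.append(f"{ct}_{suffix}")
            blocks.append(vec.reindex(genes).to_numpy(dtype=float))
    raw = np.column_stack(blocks)

    std = Standardizer().fit(raw, train_rows)
    values = std.transform(raw)
    values = np.where(np.isnan(values), 0.0, values)
    fm = FeatureMatrix(
        genes=list(genes), values=values, column_names=cols, family_tag="core"
    )
    return fm, std


def incidence_features(hg: Hypergraph) -> FeatureMatrix:
    """The gene x pathway incidence matrix itself as binary features (d = m)."""
    return FeatureMatrix(
        genes=list(hg.genes),
        values=np.asarray(hg.incidence.todense()),
        column_names=list(hg.pathway_ids),
        family_tag="incidence",
    )


def load_comprehensive_features(
    table: str | Path,
    genes: list[str] | None = None,
    expected_cols: int = 44,
    train_rows: np.ndarray | None = None,
) -> tuple[FeatureMatrix, Standardizer]:
    """Load a curated per-gene annotation table (44 columns in the reference set).

    The file is delimited text with a header and a gene-symbol column named
    ``gene`` or ``symbol`` (case-insensitive).  Columns are coerced to
    numeric; all-NaN columns are dropped with a warning; remaining missing
    values are imputed with the per-column median of training genes, then
    z-scored with training-only statistics.
    """
    df = pd.read_csv(table, sep=None, engine="python")
    gene_col = next(
        (c for c in df.columns if c.lower() in {"gene", "symbol", "gene_symbol"}), None
    )
    if gene_col is None:
        raise ValueError("no gene column found (expected 'gene' or 'symbol')")
    df[gene_col] = df[gene_col].astype(str).str.upper()
    df = df.drop_duplicates(subset=gene_col).set_index(gene_col)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    dead = [c for c in numeric.columns if numeric[c].isna().all()]
    if dead:
        warnings.warn(f"dropping non-numeric/all-NaN columns: {dead}", stacklevel=2)
        numeric = numeric.drop(columns=dead)
    if expected_cols is not None and numeric.shape[1] != expected_cols:
        warnings.warn(
            f"expected {expected_cols} feature columns, found {numeric.shape[1]}",
            stacklevel=2,
        )

    if genes is None:
        genes = list(numeric.index)
    raw = numeric.reindex(genes).to_numpy(dtype=float)

    train = raw if train_rows is None else raw[train_rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(train, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    filled = np.where(np.isnan(raw), medians, raw)

    std = Standardizer().fit(filled, train_rows)
    fm = FeatureMatrix(
        genes=list(genes),
        values=std.transform(filled),
        column_names=list(numeric.columns),
        family_tag="comprehensive",
    )
    return fm, std


def combine_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Horizontally concatenate feature families sharing one gene order.

    A gene-order mismatch is an error — no silent reindexing.  Duplicate
    column names across families are suffixed with the family tag.
    """
    if not parts:
        raise ValueError("need at least one feature matrix")
    ref = parts[0].genes
    for fm in parts[1:]:
        if fm.genes != ref:
            raise ValueError("gene order mismatch between feature matrices")
    if len(parts) == 1:
        fm = parts[0]
        return FeatureMatrix(
            genes=list(fm.genes),
            values=fm.values.copy(),
            column_names=list(fm.column_names),
            family_tag="combined",
        )
    seen: set[str] = set()
    cols: list[str] = []
    for fm in parts:
        for c in fm.column_names:
            name = c if c not in seen else f"{c}_{fm.family_tag}"
            seen.add(name)
            cols.append(name)
    values = np.hstack([fm.values for fm in parts])
    return FeatureMatrix(
        genes=list(ref), values=values, column_names=cols, family_tag="combined"
    )


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = fm.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def load_feature_matrix(path: str | Path, family_tag: str = "combined") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return FeatureMatrix(
        genes=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        column_names=[str(c) for c in df.columns],
        family_tag=family_tag,
    )
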