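"""End-to-end pipeline: simulate -> build-graph -> featurize -> labels ->
train -> evaluate -> rank.

Every stage writes its artifacts under ``<out>/<stage>/`` together with a
``manifest.json`` recording the seed, the stage's config echo and SHA-256
hashes of its inputs.  Re-running a stage with identical config and inputs
is a no-op unless forced, which keeps multi-seed protocol runs reproducible
and cheap to resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import evaluation, features, hypergraph, labels as labels_mod, model, synthetic

logger = logging.getLogger(__name__)

STAGES = ["simulate", "build-graph", "featurize", "labels", "train", "evaluate", "rank"]

__all__ = ["RunConfig", "run_pipeline", "run_stage", "STAGES", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage cannot run (missing upstream artifact, bad stage list, ...)."""


class SyntheticBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 2000
    n_pathways: int = 200
    edge_size_min: int = 5
    edge_size_max: int = 50
    n_driver_pathways: int = 20
    driver_fraction_within: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_cancer_types: int = 16
    samples_per_type: int = 20

    def to_spec(self, seed: int) -> synthetic.SyntheticSpec:
        return synthetic.SyntheticSpec(
            n_genes=self.n_genes,
            n_pathways=self.n_pathways,
            edge_size_range=(self.edge_size_min, self.edge_size_max),
            n_driver_pathways=self.n_driver_pathways,
            driver_fraction_within=self.driver_fraction_within,
            effect_size=self.effect_size,
            noise_sd=self.noise_sd,
            n_cancer_types=self.n_cancer_types,
            samples_per_type=self.samples_per_type,
            seed=seed,
        )


class GraphBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gmt: Optional[str] = None  # default: the simulate stage's GMT
    blacklist: list[str] = list(hypergraph.DEFAULT_CANCER_TERMS)
    min_edge_size: int = 2


class FeatureBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "pan"  # pan | specific
    cancer_type: Optional[str] = None
    include_incidence: bool = False
    comprehensive_table: Optional[str] = None
    omics_dir: Optional[str] = None  # default: the simulate stage's omics dir


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_layers: int = 2
    hidden_dim: int = 128
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 300
    patience: int = 30
    activation: str = "relu"

    def to_config(self, seed: int) -> model.ModelConfig:
        return model.ModelConfig(seed=seed, **self.model_dump())


class CVBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outer_folds: int = 5
    inner_folds: int = 4
    seeds: list[int] = [0, 1, 2, 3, 4]
    grid: dict[str, list] = {}

    def to_plan(self) -> evaluation.CVPlan:
        return evaluation.CVPlan(**self.model_dump())


class RunConfig(BaseModel):
    """Strict YAML-backed run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "runs/default"
    seed: int = 0
    log_level: str = "INFO"
    synthetic: SyntheticBlock = SyntheticBlock()
    graph: GraphBlock = GraphBlock()
    features: FeatureBlock = FeatureBlock()
    model: ModelBlock = ModelBlock()
    cv: CVBlock = CVBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_inputs(paths: list[Path]) -> dict[str, str]:
    out = {}
    for p in sorted(paths):
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file() and f.name != "manifest.json":
                    out[str(f)] = _sha256(f)
        elif p.is_file():
            out[str(p)] = _sha256(p)
    return out


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.out_dir) / stage


def _manifest_matches(stage_dir: Path, manifest: dict) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()) == manifest
    except json.JSONDecodeError:
        return False


def _write_manifest(stage_dir: Path, manifest: dict) -> None:
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _load_core_inputs(cfg: RunConfig):
    graph_dir = _require(_stage_dir(cfg, "build-graph") / "graph", "build-graph")
    hg = hypergraph.load_hypergraph(graph_dir)
    fm = features.load_feature_matrix(
        _require(_stage_dir(cfg, "featurize") / "features.tsv", "featurize")
    )
    ls = labels_mod.load_labelset(
        _require(_stage_dir(cfg, "labels") / "labels.tsv", "labels")
    )
    if fm.genes != hg.genes:
        raise PipelineError("feature matrix gene order differs from graph")
    return hg, fm, ls


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig) -> list[Path]:
    out = _stage_dir(cfg, "simulate")
    synthetic.write_synthetic_dataset(cfg.synthetic.to_spec(cfg.seed), out)
    return []


def _stage_build_graph(cfg: RunConfig) -> list[Path]:
    gmt = Path(cfg.graph.gmt) if cfg.graph.gmt else _require(
        _stage_dir(cfg, "simulate") / "pathways.gmt", "simulate"
    )
    pc = hypergraph.parse_gmt(gmt)
    pc, removed = hypergraph.filter_cancer_terms(pc, cfg.graph.blacklist)
    logger.info("build-graph: removed %d cancer-term pathways", removed)
    hg = hypergraph.build_hypergraph(pc, min_edge_size=cfg.graph.min_edge_size)
    hypergraph.save_hypergraph(hg, _stage_dir(cfg, "build-graph") / "graph")
    return [gmt]


def _stage_featurize(cfg: RunConfig) -> list[Path]:
    graph_dir = _require(_stage_dir(cfg, "build-graph") / "graph", "build-graph")
    hg = hypergraph.load_hypergraph(graph_dir)
    omics_root = Path(cfg.features.omics_dir) if cfg.features.omics_dir else _require(
        _stage_dir(cfg, "simulate") / "omics", "simulate"
    )

    type_dirs = sorted(d for d in omics_root.iterdir() if d.is_dir())
    if cfg.features.mode == "specific":
        if cfg.features.cancer_type is None:
            raise PipelineError("specific mode requires features.cancer_type")
        type_dirs = [d for d in type_dirs if d.name == cfg.features.cancer_type]
        if not type_dirs:
            raise PipelineError(f"cancer type {cfg.features.cancer_type!r} not found")

    per_cancer = []
    for d in type_dirs:
        tables = _read_omics_dir(d)
        per_cancer.append(
            (
                d.name,
                (
                    features.mutation_features(tables),
                    features.expression_features(tables),
                    features.methylation_features(tables),
                ),
            )
        )
    fm, _ = features.assemble_core_features(per_cancer, hg.genes, mode=cfg.features.mode)

    parts = [fm]
    if cfg.features.include_incidence:
        parts.append(features.incidence_features(hg))
    if cfg.features.comprehensive_table:
        comp, _ = features.load_comprehensive_features(
            cfg.features.comprehensive_table, genes=hg.genes
        )
        parts.append(comp)
    combined = features.combine_features(parts) if len(parts) > 1 else fm

    out = _stage_dir(cfg, "featurize")
    out.mkdir(parents=True, exist_ok=True)
    features.save_feature_matrix(combined, out / "features.tsv")
    return [graph_dir, omics_root]


def _read_omics_dir(d: Path) -> features.OmicsTables:
    read = lambda name: pd.read_csv(d / name, sep="\t", index_col=0)
    return features.OmicsTables(
        mutation_counts=read("mutation_counts.tsv"),
        gene_lengths=read("gene_lengths.tsv")["length_bp"],
        tumor_expr=read("tumor_expr.tsv"),
        normal_expr=read("normal_expr.tsv"),
        tumor_beta=read("tumor_beta.tsv"),
        normal_beta=read("normal_beta.tsv"),
        cancer_type=d.name,
    )


def _stage_labels(cfg: RunConfig) -> list[Path]:
    graph_dir = _require(_stage_dir(cfg, "build-graph") / "graph", "build-graph")
    hg = hypergraph.load_hypergraph(graph_dir)
    src = _require(_stage_dir(cfg, "simulate") / "labels.tsv", "simulate")
    raw = labels_mod.load_labelset(src)
    ls = labels_mod.assemble_labelset(hg.genes, raw.positives, raw.negatives)
    out = _stage_dir(cfg, "labels")
    out.mkdir(parents=True, exist_ok=True)
    labels_mod.save_labelset(ls, out / "labels.tsv")
    return [graph_dir, src]


def _stage_train(cfg: RunConfig) -> list[Path]:
    hg, fm, ls = _load_core_inputs(cfg)
    y, labeled = model._labels_vector(hg.genes, ls)
    labeled_idx = np.flatnonzero(labeled)
    folds = evaluation.stratified_splits(y[labeled_idx], 5, seed=cfg.seed)
    val_idx = labeled_idx[folds[0]]
    train_idx = np.setdiff1d(labeled_idx, val_idx)

    train_pos = {hg.genes[i] for i in train_idx if y[i] == 1}
    hg_w = hypergraph.weight_hyperedges(hg, train_pos)
    scorer = model.train(hg_w, fm, ls, train_idx, val_idx,
                         cfg.model.to_config(cfg.seed))
    out = _stage_dir(cfg, "train")
    out.mkdir(parents=True, exist_ok=True)
    model.save_checkpoint(scorer, out / "model.npz")
    hypergraph.save_hypergraph(hg_w, out / "weighted_graph")
    return [
        _stage_dir(cfg, "build-graph") / "graph",
        _stage_dir(cfg, "featurize") / "features.tsv",
        _stage_dir(cfg, "labels") / "labels.tsv",
    ]


def _stage_evaluate(cfg: RunConfig) -> list[Path]:
    hg, fm, ls = _load_core_inputs(cfg)
    report = evaluation.nested_cv(
        hg, fm, ls, cfg.cv.to_plan(), cfg.model.to_config(cfg.seed)
    )
    out = _stage_dir(cfg, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return [
        _stage_dir(cfg, "build-graph") / "graph",
        _stage_dir(cfg, "featurize") / "features.tsv",
        _stage_dir(cfg, "labels") / "labels.tsv",
    ]


def _stage_rank(cfg: RunConfig) -> list[Path]:
    hg, fm, ls = _load_core_inputs(cfg)
    ckpt = _require(_stage_dir(cfg, "train") / "model.npz", "train")
    graph_dir = _require(_stage_dir(cfg, "train") / "weighted_graph", "train")
    scorer = model.load_checkpoint(ckpt)
    hg_w = hypergraph.load_hypergraph(graph_dir)
    scores = model.score_genes(scorer, hg_w, fm)

    ranked = evaluation.rank_genes(hg.genes, scores)
    score_map = dict(zip(hg.genes, scores))
    label_map = {g: 1 for g in ls.positives}
    label_map.update({g: 0 for g in ls.negatives})
    out = _stage_dir(cfg, "rank")
    out.mkdir(parents=True, exist_ok=True)
    with (out / "ranked.tsv").open("w") as fh:
        fh.write("gene\tscore\trank\tlabel\n")
        for r, g in enumerate(ranked, start=1):
            fh.write(f"{g}\t{score_map[g]:.8f}\t{r}\t{label_map.get(g, -1)}\n")
    return [ckpt, graph_dir]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "build-graph": _stage_build_graph,
    "featurize": _stage_featurize,
    "labels": _stage_labels,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "rank": _stage_rank,
}


def run_stage(cfg: RunConfig, stage: str, force: bool = False) -> str:
    """Run one stage; returns 'ran' or 'up-to-date'."""
    if stage not in _STAGE_FNS:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
    stage_dir = _stage_dir(cfg, stage)
    stage_dir.mkdir(parents=True, exist_ok=True)

    # hash-the-inputs-first: the stage fn returns the inputs it consumed, so
    # run it, then record; for idempotence we pre-compute on a dry pass of
    # declared inputs via the stage function's contract.
    fn = _STAGE_FNS[stage]
    echo = cfg.model_dump()
    probe = {
        "stage": stage,
        "seed": cfg.seed,
        "config": echo,
    }
    mf = stage_dir / "manifest.json"
    if not force and mf.exists():
        try:
            existing = json.loads(mf.read_text())
        except json.JSONDecodeError:
            existing = None
        if (
            existing
            and existing.get("stage") == stage
            and existing.get("seed") == cfg.seed
            and existing.get("config") == echo
            and existing.get("inputs") == _hash_inputs(
                [Path(p) for p in existing.get("inputs", {})]
            )
        ):
            logger.info("stage %s up-to-date", stage)
            return "up-to-date"

    inputs = fn(cfg)
    probe["inputs"] = _hash_inputs(inputs)
    _write_manifest(stage_dir, probe)
    return "ran"


def run_pipeline(
    cfg: RunConfig, stages: list[str] | None = None, force: bool = False
) -> dict[str, str]:
    """Run a contiguous, dependency-ordered subset of stages.

    Raises :class:`PipelineError` for out-of-order or non-contiguous stage
    lists, or when an upstream artifact is missing.
    """
    stages = stages or STAGES
    idx = []
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
        idx.append(STAGES.index(s))
    if idx != sorted(idx) or any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise PipelineError(f"stages must be a contiguous ordered subset of {STAGES}")
    return {s: run_stage(cfg, s, force=force) for s in stages}
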