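"""Classification and ranking metrics plus the nested cross-validation protocol.

Evaluation follows a 5-fold outer / 4-fold inner stratified cross-validation
repeated over several seeds.  Within each outer round, hyperedge weights are
recomputed from the outer-training positives only — validation and test
labels never touch graph construction — hyperparameters are selected on the
inner folds by mean validation AUPRC, the model is retrained on the full
outer-training set, and the held-out fold is scored.  AUROC, AUPRC and F1
are aggregated as mean ± std over folds x seeds; Precision@K and Hits@K are
computed on the pooled held-out ranking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import FeatureMatrix
from .hypergraph import Hypergraph, weight_hyperedges
from .labels import LabelSet
from .model import ModelConfig, TrainedScorer, _labels_vector, score_genes, train

__all__ = [
    "CVPlan",
    "EvalReport",
    "auroc",
    "auprc",
    "f1_at_threshold",
    "rank_genes",
    "hits_at_k",
    "precision_at_k",
    "stratified_splits",
    "nested_cv",
]


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("auroc needs both a positive and a negative example")
    return float(roc_auc_score(labels, scores))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve (average-precision form).

    Mean over positives of the precision at each positive's rank, scores
    sorted descending with ties broken by stable sort (original order).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("auprc needs at least one positive example")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    ranks = np.arange(1, len(y) + 1)
    cum_pos = np.cumsum(y)
    precision_at_pos = cum_pos[y == 1] / ranks[y == 1]
    return float(precision_at_pos.mean())


def f1_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """F1 with predicted positive = score >= threshold; 0 if nothing predicted."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if tp + fp == 0 or tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def rank_genes(genes: list[str], scores: np.ndarray) -> list[str]:
    """Genes sorted by descending score, ties broken by ascending gene id."""
    genes_arr = np.asarray(genes)
    order = np.lexsort((genes_arr, -np.asarray(scores, dtype=float)))
    return [str(g) for g in genes_arr[order]]


def _clamp_k(k: int, length: int) -> int:
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > length:
        warnings.warn(f"K={k} exceeds ranking length {length}; clamping", stacklevel=3)
        return length
    return k


def hits_at_k(ranked_genes: list[str], known_positives: set[str], k: int) -> int:
    """Number of known positives among the top-K of a ranked gene list."""
    k = _clamp_k(k, len(ranked_genes))
    return len(set(ranked_genes[:k]) & set(known_positives))


def precision_at_k(ranked_genes: list[str], known_positives: set[str], k: int) -> float:
    """Hits@K / K."""
    k = _clamp_k(k, len(ranked_genes))
    return hits_at_k(ranked_genes, known_positives, k) / k


def stratified_splits(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deal shuffled positives and negatives round-robin into k folds.

    Fold class counts differ by at most one, so the positive fraction is
    preserved as closely as integer arithmetic allows.  Deterministic given
    the seed.
    """
    y = np.asarray(y).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"need >= {k} members of each class for {k}-fold splits")
    rng = np.random.default_rng(seed)
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, idx in enumerate(pos):
        folds[i % k].append(int(idx))
    for i, idx in enumerate(neg):
        folds[i % k].append(int(idx))
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CVPlan:
    """Nested cross-validation layout: outer folds, inner folds, seeds, grid.

    An empty grid skips hyperparameter search: the base config is used and
    the first inner fold serves as the early-stopping validation split.
    """

    outer_folds: int = 5
    inner_folds: int = 4
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    grid: dict[str, list] = field(default_factory=dict)

    def candidates(self, base: ModelConfig) -> list[ModelConfig]:
        if not self.grid:
            return [base]
        keys = sorted(self.grid)
        return [
            base.replace(**dict(zip(keys, combo)))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class EvalReport:
    """Per-fold metrics, aggregates, ranking curves and the ranked gene table."""

    per_fold_metrics: pd.DataFrame
    ranking_metrics: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    ranked_genes: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "aggregate": {m: {"mean": mu, "std": sd} for m, (mu, sd) in self.aggregate.items()},
            "per_fold": self.per_fold_metrics.to_dict(orient="records"),
            "ranking": self.ranking_metrics.to_dict(orient="records"),
            "ranked_genes": self.ranked_genes.to_dict(orient="records"),
        }


def _run_outer_fold(
    hg: Hypergraph,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    labeled_idx: np.ndarray,
    test_pos_in_labeled: np.ndarray,
    plan: CVPlan,
    cfg_base: ModelConfig,
    seed: int,
) -> tuple[TrainedScorer, np.ndarray, Hypergraph, ModelConfig]:
    """Train on one outer round using training labels only; score all genes.

    ``test_pos_in_labeled`` are positions into ``labeled_idx``.  Only the
    *training* portion of ``y`` is ever read: hyperedge weights, inner
    splits, hyperparameter selection and early stopping all derive from it,
    which is what makes the leakage invariants hold exactly.
    """
    test_mask_lab = np.zeros(len(labeled_idx), dtype=bool)
    test_mask_lab[test_pos_in_labeled] = True
    train_lab_pos = np.flatnonzero(~test_mask_lab)
    train_idx = labeled_idx[train_lab_pos]

    train_positives = {hg.genes[i] for i in train_idx if y[i] == 1}
    hg_fold = weight_hyperedges(hg, train_positives)

    inner = stratified_splits(y[train_idx], plan.inner_folds, seed=seed + 1)
    candidates = plan.candidates(cfg_base)

    if len(candidates) > 1:
        mean_scores = []
        for cand in candidates:
            fold_scores = []
            for inner_fold in inner:
                val_idx = train_idx[inner_fold]
                tr_idx = np.setdiff1d(train_idx, val_idx)
                cfg_i = cand.replace(seed=seed)
                scorer = train(hg_fold, X, _as_labelset(hg, y, train_idx), tr_idx, val_idx, cfg_i)
                probs = score_genes(scorer, hg_fold, X)
                fold_scores.append(auprc(probs[val_idx], y[val_idx]))
            mean_scores.append(float(np.mean(fold_scores)))
        best_cfg = candidates[int(np.argmax(mean_scores))]
    else:
        best_cfg = candidates[0]

    # final fit on the outer-training set; first inner fold = validation split
    val_idx = train_idx[inner[0]]
    tr_idx = np.setdiff1d(train_idx, val_idx)
    cfg_final = best_cfg.replace(seed=seed)
    scorer = train(hg_fold, X, _as_labelset(hg, y, train_idx), tr_idx, val_idx, cfg_final)
    probs = score_genes(scorer, hg_fold, X)
    return scorer, probs, hg_fold, cfg_final


def _as_labelset(hg: Hypergraph, y: np.ndarray, visible_idx: np.ndarray) -> LabelSet:
    """LabelSet exposing only the labels at ``visible_idx`` (rest unlabeled)."""
    visible = set(int(i) for i in visible_idx)
    pos = {hg.genes[i] for i in visible if y[i] == 1}
    neg = {hg.genes[i] for i in visible if y[i] == 0}
    unl = {g for i, g in enumerate(hg.genes) if i not in visible}
    return LabelSet(positives=pos, negatives=neg, unlabeled=unl)


def nested_cv(
    hg: Hypergraph,
    X: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    plan: CVPlan | None = None,
    cfg_base: ModelConfig | None = None,
    max_rank_k: int = 50,
) -> EvalReport:
    """Run the full nested CV protocol and aggregate classification + ranking metrics.

    Returns per-(seed, fold) AUROC/AUPRC/F1, their mean ± std, Precision@K
    and Hits@K curves for K = 1..``max_rank_k`` on the pooled held-out
    ranking (each labeled gene's held-out score averaged over seeds), and the
    pooled score-sorted gene table.
    """
    plan = plan or CVPlan()
    cfg_base = cfg_base or ModelConfig()

    y, labeled_mask = _labels_vector(hg.genes, labels)
    labeled_idx = np.flatnonzero(labeled_mask)
    n_lab = len(labeled_idx)

    rows = []
    heldout_scores = np.zeros((len(plan.seeds), n_lab))
    for s_i, seed in enumerate(plan.seeds):
        outer = stratified_splits(y[labeled_idx], plan.outer_folds, seed=seed)
        for f_i, test_pos in enumerate(outer):
            _, probs, _, cfg_used = _run_outer_fold(
                hg, X, y, labeled_idx, test_pos, plan, cfg_base, seed
            )
            test_idx = labeled_idx[test_pos]
            s, yt = probs[test_idx], y[test_idx]
            rows.append(
                {
                    "seed": seed,
                    "fold": f_i,
                    "auroc": auroc(s, yt),
                    "auprc": auprc(s, yt),
                    "f1": f1_at_threshold(s, yt),
                    "n_test": len(test_idx),
                    "hidden_dim": cfg_used.hidden_dim,
                    "learning_rate": cfg_used.learning_rate,
                    "dropout": cfg_used.dropout,
                }
            )
            heldout_scores[s_i, test_pos] = probs[test_idx]

    per_fold = pd.DataFrame(rows)
    aggregate = {
        m: (float(per_fold[m].mean()), float(per_fold[m].std(ddof=0)))
        for m in ("auroc", "auprc", "f1")
    }

    pooled = heldout_scores.mean(axis=0)
    lab_genes = [hg.genes[i] for i in labeled_idx]
    positives = {g for g, yi in zip(lab_genes, y[labeled_idx]) if yi == 1}
    ranked = rank_genes(lab_genes, pooled)
    ks = range(1, min(max_rank_k, len(ranked)) + 1)
    ranking = pd.DataFrame(
        {
            "K": list(ks),
            "hits": [hits_at_k(ranked, positives, k) for k in ks],
            "precision": [precision_at_k(ranked, positives, k) for k in ks],
        }
    )

    score_map = dict(zip(lab_genes, pooled))
    ranked_genes = pd.DataFrame(
        {
            "gene": ranked,
            "score": [score_map[g] for g in ranked],
            "label": [1 if g in positives else 0 for g in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
    return EvalReport(
        per_fold_metrics=per_fold,
        ranking_metrics=ranking,
        aggregate=aggregate,
        ranked_genes=ranked_genes,
    )
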