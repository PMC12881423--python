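"""Hypergraph convolutional scorer: conv layers, readout, MLP head, training.

The network stacks hypergraph convolutions

    X^{(l+1)} = sigma( P X^{(l)} Theta_l ),   P = D_v^{-1/2} H W B^{-1} H^T D_v^{-1/2}

with dropout on each layer's input during training, concatenates the raw
features X^{(0)} with every layer's output (so isolated genes keep their own
signal), projects the concatenation to ``hidden_dim`` (the readout), and
feeds it to a two-layer MLP with a logistic output — the probability that
each gene is a cancer driver.  Training minimizes binary cross-entropy over
the labeled genes only; unlabeled genes still shape every embedding through
the propagation operator.

Everything is dense/sparse numpy with analytically derived gradients and a
decoupled-weight-decay Adam (AdamW) optimizer; the numeric gradient check in
the test suite pins the backward pass to the forward definition.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .features import FeatureMatrix
from .hypergraph import Hypergraph, PropagationOperator, propagation_operator
from .labels import LabelSet

__all__ = [
    "ModelConfig",
    "TrainedScorer",
    "hypergcn_layer",
    "readout",
    "mlp_head",
    "masked_bce",
    "train",
    "score_genes",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS_PROB = 1e-7  # probability clipping for BCE numerical safety

_ACTIVATIONS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
    "identity": (lambda a: a, lambda a: np.ones_like(a)),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the scorer and its training loop.

    Defaults follow the reference protocol: learning rate 1e-3, dropout 0.5,
    hidden width 128, at most 300 epochs with early stopping (patience 30),
    AdamW weight decay 5e-4, two convolution layers.
    """

    n_layers: int = 2
    hidden_dim: int = 128
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def replace(self, **kwargs) -> "ModelConfig":
        d = asdict(self)
        d.update(kwargs)
        return ModelConfig(**d)


@dataclass
class TrainedScorer:
    """Fitted parameters plus the config and per-epoch loss history."""

    params: dict[str, np.ndarray | list[np.ndarray]]
    config: ModelConfig
    genes: list[str]
    n_features: int
    training_history: list[tuple[float, float]] = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# building blocks (exposed individually; the full forward composes them)
# ---------------------------------------------------------------------------

def _dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout scale mask: 0 with prob rate, else 1/(1-rate)."""
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def hypergcn_layer(
    X_l: np.ndarray,
    P: PropagationOperator | sp.spmatrix,
    Theta: np.ndarray,
    activation: str = "relu",
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One hypergraph convolution: sigma(P . dropout(X_l) . Theta).

    Dropout hits the layer input during training only; evaluation mode is
    deterministic.
    """
    Pm = P.matrix if isinstance(P, PropagationOperator) else P
    if X_l.shape[0] != Pm.shape[0] or X_l.shape[1] != Theta.shape[0]:
        raise ValueError(
            f"shape mismatch: P {Pm.shape}, X {X_l.shape}, Theta {Theta.shape}"
        )
    act, _ = _ACTIVATIONS[activation]
    D = X_l
    if training and dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng()
        D = X_l * _dropout_mask(X_l.shape, dropout_rate, rng)
    return act(Pm @ D @ Theta)


def readout(
    layer_outputs: list[np.ndarray],
    projection: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate the raw input and every layer's embedding, project to hidden_dim.

    Including X^{(0)} gives every gene — zero-degree genes in particular — a
    path from its own features to the prediction head.
    """
    if not layer_outputs:
        raise ValueError("need at least one layer output")
    n = layer_outputs[0].shape[0]
    for Z in layer_outputs[1:]:
        if Z.shape[0] != n:
            raise ValueError("row-count mismatch in readout inputs")
    C = np.hstack(layer_outputs)
    if C.shape[1] != projection.shape[0]:
        raise ValueError("projection width does not match concatenation width")
    out = C @ projection
    if bias is not None:
        out = out + bias
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def mlp_head(
    Z: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """Two-layer MLP (hidden -> hidden/2 -> 1) with logistic output in (0,1)."""
    act, _ = _ACTIVATIONS[activation]
    h = act(Z @ W1 + b1)
    logits = (h @ W2 + b2).ravel()
    return _sigmoid(logits)


def masked_bce(probs: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean binary cross-entropy over masked (labeled) genes.

    Probabilities are clipped to [1e-7, 1-1e-7]; unlabeled genes contribute
    no loss although they participated in propagation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no genes")
    p = np.clip(probs[mask], _EPS_PROB, 1.0 - _EPS_PROB)
    y = np.asarray(labels, dtype=float)[mask]
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def init_params(n_features: int, cfg: ModelConfig, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights, zero biases."""
    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    h = cfg.hidden_dim
    dims = [n_features] + [h] * cfg.n_layers
    thetas = [glorot(dims[l], dims[l + 1]) for l in range(cfg.n_layers)]
    concat_dim = n_features + h * cfg.n_layers
    return {
        "thetas": thetas,
        "R": glorot(concat_dim, h),
        "bR": np.zeros(h),
        "W1": glorot(h, max(h // 2, 1)),
        "b1": np.zeros(max(h // 2, 1)),
        "W2": glorot(max(h // 2, 1), 1),
        "b2": np.zeros(1),
    }


def forward(
    params: dict,
    P: sp.spmatrix,
    X: np.ndarray,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass; returns (probabilities, cache for backward)."""
    act, _ = _ACTIVATIONS[cfg.activation]
    cache: dict = {"X0": X, "drops": [], "D": [], "A": [], "layers": [X]}
    X_l = X
    for Theta in params["thetas"]:
        if training and cfg.dropout > 0:
            mask = _dropout_mask(X_l.shape, cfg.dropout, rng)
        else:
            mask = None
        D = X_l if mask is None else X_l * mask
        A = P @ D @ Theta
        X_l = act(A)
        cache["drops"].append(mask)
        cache["D"].append(D)
        cache["A"].append(A)
        cache["layers"].append(X_l)

    C = np.hstack(cache["layers"])
    Z = C @ params["R"] + params["bR"]
    a1 = Z @ params["W1"] + params["b1"]
    h1 = act(a1)
    logits = (h1 @ params["W2"] + params["b2"]).ravel()
    probs = _sigmoid(logits)
    cache.update(C=C, Z=Z, a1=a1, h1=h1, logits=logits, probs=probs)
    return probs, cache


def backward(
    params: dict,
    P: sp.spmatrix,
    cache: dict,
    labels: np.ndarray,
    mask: np.ndarray,
    cfg: ModelConfig,
) -> dict:
    """Analytic gradients of masked BCE w.r.t. every parameter."""
    _, dact = _ACTIVATIONS[cfg.activation]
    mask = np.asarray(mask, dtype=bool)
    n_lab = int(mask.sum())
    y = np.asarray(labels, dtype=float)
    probs = cache["probs"]

    # d loss / d logit via the sigmoid–BCE shortcut, honoring the clip:
    # where the clip is active the loss is locally flat in p.
    dlogits = np.zeros_like(probs)
    active = mask & (probs > _EPS_PROB) & (probs < 1.0 - _EPS_PROB)
    dlogits[active] = (probs[active] - y[active]) / n_lab

    dlogits = dlogits[:, None]
    grads: dict = {}
    grads["W2"] = cache["h1"].T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dh1 = dlogits @ params["W2"].T
    da1 = dh1 * dact(cache["a1"])
    grads["W1"] = cache["Z"].T @ da1
    grads["b1"] = da1.sum(axis=0)
    dZ = da1 @ params["W1"].T
    grads["R"] = cache["C"].T @ dZ
    grads["bR"] = dZ.sum(axis=0)
    dC = dZ @ params["R"].T

    # split concat gradient back into the per-layer blocks
    widths = [Z.shape[1] for Z in cache["layers"]]
    splits = np.cumsum(widths)[:-1]
    dblocks = np.split(dC, splits, axis=1)

    grads["thetas"] = [None] * len(params["thetas"])
    dX_next = None  # gradient flowing into layer l's output from layer l+1
    for l in range(len(params["thetas"]) - 1, -1, -1):
        dXl = dblocks[l + 1] if dX_next is None else dblocks[l + 1] + dX_next
        dA = dXl * dact(cache["A"][l])
        Q = P @ dA  # P symmetric: P^T = P
        grads["thetas"][l] = cache["D"][l].T @ Q
        dD = Q @ params["thetas"][l].T
        mask_l = cache["drops"][l]
        dX_next = dD if mask_l is None else dD * mask_l
    # dX_next now holds the gradient w.r.t. X^{(0)} through the conv stack;
    # (dblocks[0] adds the readout skip path) — not needed for parameters.
    return grads


class _AdamW:
    """Adam with decoupled weight decay; decay skips bias vectors."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = _tree_map(params, np.zeros_like)
        self.v = _tree_map(params, np.zeros_like)

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, g, p, m, v in _tree_zip(grads, params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd > 0 and not key.startswith("b"):
                update = update + self.wd * p
            p -= self.lr * update


def _tree_map(tree: dict, fn):
    out = {}
    for k, val in tree.items():
        out[k] = [fn(x) for x in val] if isinstance(val, list) else fn(val)
    return out


def _tree_zip(*trees: dict):
    for k in trees[0]:
        vals = [t[k] for t in trees]
        if isinstance(vals[0], list):
            for i in range(len(vals[0])):
                yield k, *(v[i] for v in vals)
        else:
            yield k, *vals


def _labels_vector(genes: list[str], labels: LabelSet) -> tuple[np.ndarray, np.ndarray]:
    """(y, labeled_mask) over the hypergraph gene order; unlabeled y = -1."""
    y = np.full(len(genes), -1.0)
    pos, neg = labels.positives, labels.negatives
    for i, g in enumerate(genes):
        if g in pos:
            y[i] = 1.0
        elif g in neg:
            y[i] = 0.0
    return y, y >= 0


def train(
    hg: Hypergraph,
    X: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: ModelConfig | None = None,
) -> TrainedScorer:
    """Full-batch supervised training with AdamW and early stopping.

    ``train_idx``/``val_idx`` index labeled genes in the hypergraph's gene
    order and must be disjoint.  Hyperedge weights on ``hg`` are expected to
    have been computed from the training positives only (leakage contract).
    Training stops when validation loss has not improved for ``patience``
    epochs (or at ``max_epochs``) and the best-validation parameters are
    restored.  Deterministic given the config seed.
    """
    cfg = cfg or ModelConfig()
    if isinstance(X, FeatureMatrix):
        if X.genes != hg.genes:
            raise ValueError("feature matrix gene order differs from hypergraph")
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if val_idx.size == 0:
        raise ValueError("validation index set is empty")
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation indices overlap")

    y, labeled = _labels_vector(hg.genes, labels)
    for name, idx in (("train", train_idx), ("val", val_idx)):
        if not labeled[idx].all():
            raise ValueError(f"{name}_idx contains unlabeled genes")
    if len(np.unique(y[train_idx])) < 2:
        warnings.warn("training labels are single-class; fit will be degenerate",
                      stacklevel=2)

    P = propagation_operator(hg).matrix
    rng = np.random.default_rng(cfg.seed)
    params = init_params(Xv.shape[1], cfg, rng)
    opt = _AdamW(params, cfg.learning_rate, cfg.weight_decay)

    train_mask = np.zeros(len(hg.genes), dtype=bool)
    train_mask[train_idx] = True
    val_mask = np.zeros(len(hg.genes), dtype=bool)
    val_mask[val_idx] = True

    history: list[tuple[float, float]] = []
    best_val = np.inf
    best_params = None
    best_epoch = -1
    since_best = 0
    for epoch in range(cfg.max_epochs):
        probs, cache = forward(params, P, Xv, cfg, training=True, rng=rng)
        train_loss = masked_bce(probs, y, train_mask)
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}; "
                "check feature scaling and learning rate"
            )
        grads = backward(params, P, cache, y, train_mask, cfg)
        opt.step(params, grads)

        eval_probs, _ = forward(params, P, Xv, cfg, training=False)
        val_loss = masked_bce(eval_probs, y, val_mask)
        history.append((train_loss, val_loss))

        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    return TrainedScorer(
        params=best_params if best_params is not None else params,
        config=cfg,
        genes=list(hg.genes),
        n_features=Xv.shape[1],
        training_history=history,
        best_epoch=best_epoch,
    )


def score_genes(
    model: TrainedScorer, hg: Hypergraph, X: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Evaluation-mode probabilities for every gene (labeled or not)."""
    if isinstance(X, FeatureMatrix):
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
    if list(hg.genes) != model.genes:
        raise ValueError("gene order differs from the training hypergraph")
    if Xv.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {Xv.shape[1]} != {model.n_features} used in training"
        )
    P = propagation_operator(hg).matrix
    probs, _ = forward(model.params, P, Xv, model.config, training=False)
    return probs


def save_checkpoint(model: TrainedScorer, path: str | Path) -> None:
    """Single-file archive: config/meta JSON plus the weight arrays."""
    arrays = {}
    for i, th in enumerate(model.params["thetas"]):
        arrays[f"theta_{i}"] = th
    for k in ("R", "bR", "W1", "b1", "W2", "b2"):
        arrays[k] = model.params[k]
    meta = {
        "config": asdict(model.config),
        "genes": model.genes,
        "n_features": model.n_features,
        "best_epoch": model.best_epoch,
        "training_history": model.training_history,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainedScorer:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]))
        cfg = ModelConfig(**meta["config"])
        thetas = [data[f"theta_{i}"] for i in range(cfg.n_layers)]
        params = {k: data[k] for k in ("R", "bR", "W1", "b1", "W2", "b2")}
        params["thetas"] = thetas
    return TrainedScorer(
        params=params,
        config=cfg,
        genes=meta["genes"],
        n_features=meta["n_features"],
        training_history=[tuple(h) for h in meta["training_history"]],
        best_epoch=meta["best_epoch"],
    )
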