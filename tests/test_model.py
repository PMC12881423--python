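"""Network building blocks, gradients, training loop, determinism."""

import numpy as np
import pytest

from hyperdriver import (
    LabelSet,
    ModelConfig,
    hypergcn_layer,
    masked_bce,
    mlp_head,
    propagation_operator,
    readout,
    score_genes,
    train,
)
from hyperdriver.hypergraph import hypergraph_from_memberships
from hyperdriver.model import (
    backward,
    forward,
    init_params,
    load_checkpoint,
    save_checkpoint,
)


def full_edge_hg(n=3):
    return hypergraph_from_memberships(
        [f"G{i}" for i in range(n)], ["P0"], [list(range(n))]
    )


def toy_5gene_2edge():
    """5 genes, 2 overlapping hyperedges, one isolated gene."""
    return hypergraph_from_memberships(
        [f"G{i}" for i in range(5)], ["P0", "P1"], [[0, 1, 2], [2, 3]]
    )


class TestHypergcnLayer:
    def test_full_hyperedge_averages_columns(self):
        P = propagation_operator(full_edge_hg(3))
        X = np.array([[1.0, 2.0], [4.0, 5.0], [7.0, 8.0]])
        out = hypergcn_layer(X, P, np.eye(2), activation="identity")
        assert np.allclose(out, np.tile(X.mean(axis=0), (3, 1)))

    def test_zero_input_zero_output(self):
        P = propagation_operator(full_edge_hg(3))
        out = hypergcn_layer(np.zeros((3, 2)), P, np.ones((2, 4)))
        assert np.all(out == 0)

    def test_relu_clamps_negative_preactivations(self):
        P = propagation_operator(full_edge_hg(3))
        X = -np.ones((3, 2))
        out = hypergcn_layer(X, P, np.eye(2), activation="relu")
        assert np.all(out == 0)

    def test_shape_mismatch_rejected(self):
        P = propagation_operator(full_edge_hg(3))
        with pytest.raises(ValueError, match="shape"):
            hypergcn_layer(np.zeros((4, 2)), P, np.eye(2))

    def test_eval_mode_ignores_dropout(self):
        P = propagation_operator(full_edge_hg(3))
        X = np.ones((3, 2))
        a = hypergcn_layer(X, P, np.eye(2), dropout_rate=0.9, training=False)
        b = hypergcn_layer(X, P, np.eye(2), dropout_rate=0.0, training=False)
        assert np.array_equal(a, b)


class TestReadout:
    def test_concat_then_project_widths(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=(7, w)) for w in (48, 128, 128)]
        R = rng.normal(size=(304, 128))
        assert readout(mats, R).shape == (7, 128)

    def test_identity_projection_recovers_input(self):
        X = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(readout([X], np.eye(4)), X)

    def test_isolated_gene_keeps_raw_features(self):
        hg = hypergraph_from_memberships(["A", "B", "C"], ["P0"], [[0, 1]])
        P = propagation_operator(hg)
        X0 = np.array([[1.0], [2.0], [5.0]])
        X1 = hypergcn_layer(X0, P, np.ones((1, 2)), activation="identity")
        assert np.all(X1[2] == 0)  # zero-degree gene receives nothing
        R = np.zeros((3, 2))
        R[0, 0] = 1.0  # projection reads only the raw-feature block
        Z = readout([X0, X1], R)
        assert Z[2, 0] == 5.0

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row-count"):
            readout([np.zeros((3, 2)), np.zeros((4, 2))], np.zeros((4, 1)))


class TestMlpHead:
    def test_zero_weights_give_half(self):
        Z = np.random.default_rng(0).normal(size=(5, 4))
        p = mlp_head(Z, np.zeros((4, 2)), np.zeros(2), np.zeros((2, 1)), np.zeros(1))
        assert np.allclose(p, 0.5)

    def test_outputs_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        p = mlp_head(
            rng.normal(size=(20, 4)),
            rng.normal(size=(4, 2)), rng.normal(size=2),
            rng.normal(size=(2, 1)), rng.normal(size=1),
        )
        assert np.all((p > 0) & (p < 1))

    def test_monotone_in_final_logit(self):
        Z = np.ones((1, 2))
        W1, b1 = np.eye(2), np.zeros(2)
        W2 = np.ones((2, 1))
        p_low = mlp_head(Z, W1, b1, W2, np.array([0.0]))
        p_high = mlp_head(Z, W1, b1, W2, np.array([1.0]))
        assert p_high > p_low


class TestMaskedBce:
    def test_perfect_fit_near_zero(self):
        probs = np.array([1.0, 0.0, 0.5])
        labels = np.array([1.0, 0.0, 1.0])
        mask = np.array([True, True, False])
        assert masked_bce(probs, labels, mask) < 1e-5

    def test_uninformative_prediction_is_log2(self):
        probs = np.full(4, 0.5)
        labels = np.array([1.0, 0.0, 1.0, 0.0])
        assert masked_bce(probs, labels, np.ones(4, bool)) == pytest.approx(np.log(2))

    def test_masking_ignores_unlabeled_predictions(self):
        labels = np.array([1.0, 0.0, -1.0])
        mask = np.array([True, True, False])
        a = masked_bce(np.array([0.9, 0.1, 0.99]), labels, mask)
        b = masked_bce(np.array([0.9, 0.1, 0.01]), labels, mask)
        assert a == b

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_bce(np.array([0.5]), np.array([1.0]), np.array([False]))


class TestGradients:
    def test_numeric_matches_analytic_on_toy(self):
        """Central-difference check of d(masked BCE)/d(params) on a 5-gene toy."""
        hg = toy_5gene_2edge()
        P = propagation_operator(hg).matrix
        rng = np.random.default_rng(42)
        cfg = ModelConfig(n_layers=2, hidden_dim=4, dropout=0.0, seed=0)
        X = rng.normal(size=(5, 3))
        y = np.array([1.0, 0.0, 1.0, 0.0, -1.0])
        mask = y >= 0
        params = init_params(3, cfg, rng)

        _, cache = forward(params, P, X, cfg, training=False)
        grads = backward(params, P, cache, y, mask, cfg)

        def loss_fn():
            probs, _ = forward(params, P, X, cfg, training=False)
            return masked_bce(probs, y, mask)

        eps = 1e-6
        for key, g, p in _iter_params(grads, params):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + eps
                hi = loss_fn()
                p[ix] = orig - eps
                lo = loss_fn()
                p[ix] = orig
                num = (hi - lo) / (2 * eps)
                ana = g[ix]
                # absolute floor guards exact-zero gradients (ReLU-dead paths)
                # against finite-difference roundoff noise
                rel = abs(num - ana) / max(abs(num) + abs(ana), 1e-6)
                assert rel < 1e-4, f"gradient mismatch at {key}{ix}: {num} vs {ana}"


def _iter_params(grads, params):
    for k in grads:
        if isinstance(params[k], list):
            for i, (g, p) in enumerate(zip(grads[k], params[k])):
                yield f"{k}[{i}]", g, p
        else:
            yield k, grads[k], params[k]


def _train_toy(seed=0, **cfg_kwargs):
    hg = hypergraph_from_memberships(
        [f"G{i}" for i in range(20)],
        ["P0", "P1", "P2"],
        [list(range(0, 8)), list(range(6, 14)), list(range(12, 20))],
    )
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 3))
    y = np.array([1] * 8 + [0] * 8 + [-1] * 4, dtype=float)
    X[y == 1, 0] += 3.0
    pos = {hg.genes[i] for i in range(20) if y[i] == 1}
    neg = {hg.genes[i] for i in range(20) if y[i] == 0}
    labels = LabelSet(positives=pos, negatives=neg,
                      unlabeled=set(hg.genes) - pos - neg)
    train_idx = np.array([0, 1, 2, 3, 4, 5, 8, 9, 10, 11, 12, 13])
    val_idx = np.array([6, 7, 14, 15])
    cfg = ModelConfig(hidden_dim=8, max_epochs=150, patience=30, dropout=0.1,
                      seed=seed, **cfg_kwargs)
    return train(hg, X, labels, train_idx, val_idx, cfg), hg, X, labels


class TestTraining:
    def test_same_seed_identical_history(self):
        m1, *_ = _train_toy(seed=3)
        m2, *_ = _train_toy(seed=3)
        assert m1.training_history == m2.training_history

    def test_different_seed_differs(self):
        m1, *_ = _train_toy(seed=3)
        m2, *_ = _train_toy(seed=4)
        assert m1.training_history != m2.training_history

    def test_restored_weights_are_best_validation(self):
        m, hg, X, labels = _train_toy()
        val_losses = [v for _, v in m.training_history]
        assert m.training_history[m.best_epoch][1] == min(val_losses)
        # scoring with restored params reproduces the best-epoch validation loss
        probs = score_genes(m, hg, X)
        y = np.array([1] * 8 + [0] * 8 + [-1] * 4, dtype=float)
        val_mask = np.zeros(20, bool)
        val_mask[[6, 7, 14, 15]] = True
        assert masked_bce(probs, y, val_mask) == pytest.approx(min(val_losses))

    def test_single_class_training_warns(self):
        _, hg, X, labels = _train_toy()
        cfg = ModelConfig(hidden_dim=4, max_epochs=2, patience=1, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            train(hg, X, labels, np.array([0, 1, 2]), np.array([8, 9]), cfg)

    def test_empty_validation_rejected(self):
        _, hg, X, labels = _train_toy()
        with pytest.raises(ValueError, match="validation"):
            train(hg, X, labels, np.array([0, 8]), np.array([], dtype=int),
                  ModelConfig(seed=0))

    def test_overlapping_train_val_rejected(self):
        _, hg, X, labels = _train_toy()
        with pytest.raises(ValueError, match="overlap"):
            train(hg, X, labels, np.array([0, 8]), np.array([0, 9]),
                  ModelConfig(seed=0))


class TestScoring:
    def test_scores_deterministic_and_bounded(self):
        m, hg, X, _ = _train_toy()
        p1 = score_genes(m, hg, X)
        p2 = score_genes(m, hg, X)
        assert np.array_equal(p1, p2)
        assert p1.shape == (20,)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_planted_positives_score_higher(self):
        m, hg, X, _ = _train_toy()
        p = score_genes(m, hg, X)
        assert p[:8].mean() > p[8:16].mean()

    def test_dimension_mismatch_rejected(self):
        m, hg, X, _ = _train_toy()
        with pytest.raises(ValueError, match="feature dimension"):
            score_genes(m, hg, X[:, :2])

    def test_forward_permutation_equivariance(self):
        """Permuting genes in graph and features permutes the scores."""
        m, hg, X, _ = _train_toy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(hg.n_genes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(hg.n_genes)
        H = np.asarray(hg.incidence.todense())
        hg_p = hypergraph_from_memberships(
            [hg.genes[i] for i in perm],
            list(hg.pathway_ids),
            [[int(inv[i]) for i in np.flatnonzero(H[:, j])] for j in range(hg.n_edges)],
        )
        m_p = type(m)(
            params=m.params, config=m.config,
            genes=[hg.genes[i] for i in perm], n_features=m.n_features,
        )
        p = score_genes(m, hg, X)
        p_perm = score_genes(m_p, hg_p, X[perm])
        assert np.allclose(p_perm, p[perm], atol=1e-10)


def test_checkpoint_roundtrip(tmp_path):
    m, hg, X, _ = _train_toy()
    save_checkpoint(m, tmp_path / "model.npz")
    m2 = load_checkpoint(tmp_path / "model.npz")
    assert np.array_equal(score_genes(m2, hg, X), score_genes(m, hg, X))
    assert m2.config == m.config
    assert m2.training_history == m.training_history


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_layers=0), dict(dropout=1.0), dict(learning_rate=0.0),
     dict(weight_decay=-1.0), dict(activation="swish")],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        ModelConfig(**kwargs)
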