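import numpy as np
import pytest

from caconet.dgcnn import (
    DgcnnConfig,
    _backward_batch,
    _forward_batch,
    evaluate,
    forward,
    graph_conv_forward,
    init_model,
    load_model,
    save_model,
    sort_pooling,
    train,
)
from caconet.graph_dataset import CorrelationNetwork, assemble_dataset, train_val_split


def _triple_loop_conv(A, Z, W):
    """Naive reference implementation of the propagation rule."""
    p, d = Z.shape
    w = W.shape[1]
    At = A + np.eye(p)
    deg = np.abs(At).sum(axis=1)
    ZW = np.zeros((p, w))
    for i in range(p):
        for j in range(p):
            for c in range(w):
                ZW[i, c] += At[i, j] * sum(Z[j, f] * W[f, c] for f in range(d)) / deg[i]
    return ZW


class TestGraphConv:
    def test_no_edges_identity(self):
        out = graph_conv_forward(np.zeros((2, 2)), np.eye(2), np.eye(2), "identity")
        np.testing.assert_allclose(out, np.eye(2))

    def test_single_positive_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = graph_conv_forward(A, np.eye(2), np.eye(2), "identity")
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_single_negative_edge_absolute_degree(self):
        A = np.array([[0.0, -1.0], [-1.0, 0.0]])
        out = graph_conv_forward(A, np.eye(2), np.eye(2), "identity")
        np.testing.assert_allclose(out, [[0.5, -0.5], [-0.5, 0.5]])

    def test_matches_triple_loop_on_random_graphs(self, rng):
        for _ in range(5):
            A = rng.uniform(-1, 1, (5, 5))
            A = 0.5 * (A + A.T)
            np.fill_diagonal(A, 0.0)
            Z = rng.standard_normal((5, 3))
            W = rng.standard_normal((3, 4))
            got = graph_conv_forward(A, Z, W, "identity")
            np.testing.assert_allclose(got, _triple_loop_conv(A, Z, W), atol=1e-9)


class TestSortPooling:
    def test_descending_last_channel(self):
        Z = np.array([[0.1], [0.9], [0.5]])
        out = sort_pooling([Z], k=3)
        np.testing.assert_allclose(out, [[0.9], [0.5], [0.1]])

    def test_ties_preserve_original_order(self):
        Z = np.array([[1.0, 0.5], [2.0, 0.5], [3.0, 0.5]])
        out = sort_pooling([Z], k=3)
        np.testing.assert_allclose(out[:, 0], [1.0, 2.0, 3.0])

    def test_k_one_selects_max(self):
        Z = np.array([[0.2], [0.7], [0.4]])
        out = sort_pooling([Z], k=1)
        assert out.item() == pytest.approx(0.7)

    def test_horizontal_concatenation(self):
        Z1 = np.array([[1.0], [2.0]])
        Z2 = np.array([[0.9], [0.1]])
        out = sort_pooling([Z1, Z2], k=2)
        np.testing.assert_allclose(out, [[1.0, 0.9], [2.0, 0.1]])

    def test_k_exceeds_p_errors(self):
        with pytest.raises(ValueError):
            sort_pooling([np.zeros((2, 1))], k=3)


class TestForward:
    def test_probabilities_sum_to_one(self, network_factory):
        net = network_factory(p=6)
        model = init_model(DgcnnConfig(seed=0), 6)
        res = forward(model, net)
        assert 0.0 <= res.p_disease <= 1.0
        assert res.predicted_label in (0, 1)

    def test_zero_weight_model_gives_half(self, network_factory):
        net = network_factory(p=5)
        model = init_model(DgcnnConfig(seed=0), 5)
        for key in model.weights:
            model.weights[key] = np.zeros_like(model.weights[key])
        assert forward(model, net).p_disease == pytest.approx(0.5)

    def test_forward_is_pure(self, network_factory):
        net = network_factory(p=6)
        model = init_model(DgcnnConfig(seed=1), 6)
        a = forward(model, net).p_disease
        b = forward(model, net).p_disease
        assert a == b

    def test_node_count_mismatch_errors(self, network_factory):
        model = init_model(DgcnnConfig(seed=0), 6)
        with pytest.raises(ValueError, match="nodes"):
            forward(model, network_factory(p=4))


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        cfg = DgcnnConfig(
            conv_channels=[4, 3, 1], conv1d_spec=((3, None, None), (4, 3, 1)),
            dense_units=6, dropout=0.0, seed=1,
        )
        p, B = 6, 3
        model = init_model(cfg, p)
        A = rng.uniform(-0.5, 0.5, (B, p, p))
        A = 0.5 * (A + A.transpose(0, 2, 1))
        for b in range(B):
            np.fill_diagonal(A[b], 0.0)
        y = np.array([0, 1, 1])
        X = np.eye(p)

        def loss():
            probs, cache = _forward_batch(model, A, X)
            return -np.sum(np.log(probs[np.arange(B), y])), cache

        _, cache = loss()
        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), y] -= 1.0
        grads = _backward_batch(model, cache, dlogits)
        for key, wmat in model.weights.items():
            for fi in rng.choice(wmat.size, size=min(4, wmat.size), replace=False):
                mi = np.unravel_index(fi, wmat.shape)
                eps, old = 1e-6, wmat[mi]
                wmat[mi] = old + eps
                lp, _ = loss()
                wmat[mi] = old - eps
                lm, _ = loss()
                wmat[mi] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[key][mi] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def _toy_dataset(rng, p=8, n_per_class=50, signal=0.9):
    def make(label, w):
        A = rng.normal(0, 0.05, (p, p))
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0.0)
        A = np.clip(A, -1, 1)
        A[0, 1] = A[1, 0] = w
        return CorrelationNetwork([f"t{j}" for j in range(p)], A, label)

    g0 = [make(0, 0.0) for _ in range(n_per_class)]
    g1 = [make(1, signal) for _ in range(n_per_class)]
    return assemble_dataset(g0, g1, seed=0)


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self, rng):
        ds = _toy_dataset(rng)
        train_set, val_set = train_val_split(ds, 0.8, seed=1)
        _, history = train(train_set, val_set, DgcnnConfig(epochs=30, seed=2))
        assert max(h["val"]["accuracy"] for h in history) == 1.0

    def test_shuffled_labels_stay_at_chance(self, rng):
        ds = _toy_dataset(rng)
        labels = rng.permutation(ds.labels)
        from dataclasses import replace

        from caconet.graph_dataset import GraphDataset

        shuffled = GraphDataset(
            networks=[replace(n, label=int(l)) for n, l in zip(ds.networks, labels)]
        )
        train_set, val_set = train_val_split(shuffled, 0.8, seed=1)
        _, history = train(train_set, val_set, DgcnnConfig(epochs=20, seed=3))
        assert abs(history[-1]["val"]["accuracy"] - 0.5) <= 0.2

    def test_fixed_seed_reproducible_trajectory(self, rng):
        ds = _toy_dataset(rng, n_per_class=20)
        train_set, val_set = train_val_split(ds, 0.8, seed=1)
        cfg = DgcnnConfig(epochs=3, seed=4)
        _, h1 = train(train_set, val_set, cfg)
        _, h2 = train(train_set, val_set, cfg)
        assert [h["loss"] for h in h1] == [h["loss"] for h in h2]


class TestEvaluate:
    def _dataset_with_scores(self, labels, p=4):
        taxa = [f"t{j}" for j in range(p)]
        nets = [CorrelationNetwork(taxa, np.zeros((p, p)), int(l)) for l in labels]
        from caconet.graph_dataset import GraphDataset

        return GraphDataset(networks=nets)

    class _StubModel:
        """predict_proba driven by a fixed score list."""

        def __init__(self, scores):
            self.scores = np.asarray(scores, float)

        def predict_proba(self, stack, node_info=None):
            s = self.scores[: len(stack)]
            return np.column_stack([1 - s, s])

    def test_confusion_matrix_arithmetic(self):
        # 2 TP, 1 FP, 1 FN, 4 TN -> precision = recall = 2/3
        labels = [1, 1, 1, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1]
        ds = self._dataset_with_scores(labels)
        metrics = evaluate(self._StubModel(scores), ds)
        assert metrics["precision"] == pytest.approx(2 / 3)
        assert metrics["recall"] == pytest.approx(2 / 3)
        assert metrics["accuracy"] == pytest.approx(6 / 8)

    def test_constant_score_gives_half_auc(self):
        ds = self._dataset_with_scores([0, 1, 0, 1])
        metrics = evaluate(self._StubModel([0.5] * 4), ds)
        assert metrics["auc"] == pytest.approx(0.5)

    def test_perfect_classifier_all_ones(self):
        labels = [0, 0, 1, 1]
        ds = self._dataset_with_scores(labels)
        metrics = evaluate(self._StubModel([0.1, 0.2, 0.8, 0.9]), ds)
        assert all(metrics[k] == 1.0 for k in ("accuracy", "precision", "recall", "auc"))

    def test_single_class_errors(self):
        ds = self._dataset_with_scores([1, 1, 1])
        with pytest.raises(ValueError, match="AUC"):
            evaluate(self._StubModel([0.5] * 3), ds)


def test_model_round_trip(tmp_path, network_factory):
    model = init_model(DgcnnConfig(seed=0), 5, taxon_ids=[f"t{j}" for j in range(5)])
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    net = network_factory(p=5)
    assert forward(back, net).p_disease == forward(model, net).p_disease
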