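"""Graph construction, message passing, pair scoring and training."""

import numpy as np
import pandas as pd
import pytest

from topolink.autodiff import Tensor
from topolink.graph import (
    DTIModel,
    EarlyStopping,
    ModelConfig,
    NodeInputs,
    PairClassifier,
    build_graph,
    predict_pairs,
    train_model,
)


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["drug_id", "target_id", "label"])


def toy_inputs(n_d, n_t, seed=0, f=8):
    rng = np.random.default_rng(seed)
    return NodeInputs(rng.standard_normal((n_d, f)), rng.standard_normal((n_d, f)),
                      rng.standard_normal((n_t, f)), rng.standard_normal((n_t, f)))


def toy_config(**kw):
    base = dict(latent=8, hidden1=8, hidden2=8, mlp_hidden=8, dropout=0.0,
                use_batchnorm=False, max_epochs=20, patience=20, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestBuildGraph:
    def test_message_edges_are_positive_train_only(self):
        split = {
            "train": pairs_df([("d1", "t1", 1), ("d1", "t2", 0)]),
            "val": pairs_df([("d2", "t1", 1)]),
            "test": pairs_df([("d2", "t2", 1)]),
        }
        g = build_graph(split)
        assert len(g.message_edges) == 1
        d, t = g.message_edges[0]
        assert (g.drug_ids[d], g.target_ids[t]) == ("d1", "t1")

    def test_eval_edges_never_propagate(self):
        """Removing a test edge leaves message passing untouched."""
        split = {
            "train": pairs_df([("d1", "t1", 1)]),
            "test": pairs_df([("d2", "t2", 1), ("d1", "t2", 0)]),
        }
        g_full = build_graph(split)
        g_cut = build_graph({"train": split["train"],
                             "test": pairs_df([("d1", "t2", 0)])},
                            g_full.drug_ids, g_full.target_ids)
        assert np.array_equal(g_full.adj_dt, g_cut.adj_dt)
        msg = set(map(tuple, g_full.message_edges.tolist()))
        for part in ("val", "test"):
            for d, t, _ in g_full.supervision.get(part, []):
                assert (d, t) not in msg

    def test_dangling_ids_listed(self):
        split = {"train": pairs_df([("d1", "t1", 1)])}
        with pytest.raises(ValueError, match="d1"):
            build_graph(split, drug_ids=["dX"], target_ids=["t1"])

    def test_overlapping_partitions_rejected(self):
        same = pairs_df([("d1", "t1", 1)])
        with pytest.raises(ValueError, match="overlap"):
            build_graph({"train": same, "test": same.copy()})

    def test_cold_side_nodes_are_isolated(self):
        split = {
            "train": pairs_df([("d1", "t1", 1), ("d2", "t1", 1)]),
            "test": pairs_df([("d3", "t2", 1)]),  # unseen drug and target
        }
        g = build_graph(split)
        d3, t2 = g.drug_index["d3"], g.target_index["t2"]
        assert g.adj_dt[d3].sum() == 0 and g.adj_td[t2].sum() == 0


class TestGNNForward:
    def test_edgeless_graph_uses_self_term_only(self):
        split = {"train": pairs_df([("d1", "t1", 0), ("d2", "t1", 0),
                                    ("d1", "t2", 1)])}
        g = build_graph(split)
        g.adj_dt[:] = 0
        g.adj_td[:] = 0
        inputs = toy_inputs(2, 2)
        model = DTIModel(inputs, toy_config())
        h_d, _ = model.node_embeddings(inputs, g)
        # with zero adjacency, each drug's embedding depends on its row alone
        inputs2 = NodeInputs(inputs.drug_llm.copy(), inputs.drug_topo.copy(),
                             inputs.target_llm * 100, inputs.target_topo * 100)
        model2 = DTIModel(inputs, toy_config())  # same seed, same params
        h_d2, _ = model2.node_embeddings(inputs2, g)
        assert np.allclose(h_d.data, h_d2.data)

    def test_neighbor_mean_hand_computed(self):
        """One drug linked to two identical targets: the neighbour mean equals
        either target vector; identity weights make the layer arithmetic
        checkable by hand."""
        split = {"train": pairs_df([("d1", "t1", 1), ("d1", "t2", 1)])}
        g = build_graph(split)
        inputs = toy_inputs(1, 2, f=4)
        inputs.target_llm[1] = inputs.target_llm[0]
        inputs.target_topo[1] = inputs.target_topo[0]
        cfg = toy_config(latent=4, hidden1=4, hidden2=4)
        model = DTIModel(inputs, cfg)

        f_d, f_t = model.fused_features(inputs)
        eye = np.eye(4)
        for layer in (model.sage1, model.sage2):
            for lin in (layer.self_d, layer.nbr_d, layer.self_t, layer.nbr_t):
                lin.W.data = eye.copy()
                lin.b.data = np.zeros(4)
        h_d, _ = model.node_embeddings(inputs, g)
        expected = np.maximum(f_d.data[0] + f_t.data[0], 0)       # layer 1
        t_after1 = np.maximum(f_t.data[0] + f_d.data[0], 0)
        expected = np.maximum(expected + t_after1, 0)             # layer 2
        assert np.allclose(h_d.data[0], expected)

    def test_neighbor_permutation_invariance(self):
        rows = [("d1", f"t{i}", 1) for i in range(5)]
        g1 = build_graph({"train": pairs_df(rows)})
        g2 = build_graph({"train": pairs_df(rows[::-1])})
        inputs = toy_inputs(1, 5)
        m1 = DTIModel(inputs, toy_config())
        m2 = DTIModel(inputs, toy_config())
        h1, _ = m1.node_embeddings(inputs, g1)
        h2, _ = m2.node_embeddings(inputs, g2)
        assert np.allclose(h1.data, h2.data)


class TestPredictPairs:
    def test_zero_classifier_gives_half(self):
        clf = PairClassifier(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 1)),
                             np.zeros(1))
        emb_d = {"d1": np.ones(2)}
        emb_t = {"t1": np.ones(2)}
        probs = predict_pairs(emb_d, emb_t, [("d1", "t1")], clf)
        assert probs.tolist() == [0.5]

    def test_probabilities_in_open_interval(self, rng):
        clf = PairClassifier(rng.standard_normal((4, 3)), rng.standard_normal(3),
                             rng.standard_normal((3, 1)), rng.standard_normal(1))
        emb_d = {f"d{i}": rng.standard_normal(2) for i in range(20)}
        emb_t = {f"t{i}": rng.standard_normal(2) for i in range(20)}
        probs = predict_pairs(emb_d, emb_t,
                              [(f"d{i}", f"t{i}") for i in range(20)], clf)
        assert np.all((probs > 0) & (probs < 1))

    def test_hand_computed_toy(self):
        clf = PairClassifier(np.array([[1.0], [0.0], [0.0], [1.0]]),
                             np.array([0.0]), np.array([[2.0]]), np.array([-1.0]))
        emb_d = {"d": np.array([0.5, 9.0])}
        emb_t = {"t": np.array([9.0, 0.25])}
        # h = relu(0.5 + 0.25) = 0.75; logit = 1.5 - 1 = 0.5
        probs = predict_pairs(emb_d, emb_t, [("d", "t")], clf)
        assert probs[0] == pytest.approx(1 / (1 + np.exp(-0.5)))

    def test_unknown_id_raises(self):
        clf = PairClassifier(np.zeros((4, 1)), np.zeros(1), np.zeros((1, 1)),
                             np.zeros(1))
        with pytest.raises(KeyError):
            predict_pairs({"d": np.ones(2)}, {"t": np.ones(2)}, [("dX", "t")], clf)


class TestEarlyStopping:
    def test_strictly_increasing_losses_stop_after_patience(self):
        stopper = EarlyStopping(patience=5)
        epochs_run = 0
        for loss in [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7]:
            epochs_run += 1
            if stopper.update(loss):
                break
        # first epoch improves; five consecutive non-improvements stop at 1+5
        assert epochs_run == 6

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        assert [stopper.update(v) for v in [1.0, 1.1, 0.9, 1.0, 1.05]] == \
            [False, False, False, False, True]


class TestTraining:
    def _separable_setup(self):
        rng = np.random.default_rng(5)
        n_d = n_t = 6
        latent = rng.standard_normal((n_d, 2)), rng.standard_normal((n_t, 2))
        rows = []
        for i in range(n_d):
            for j in range(n_t):
                label = int(latent[0][i] @ latent[1][j] > 0)
                rows.append((f"d{i}", f"t{j}", label))
        pairs = pairs_df(rows)
        inputs = NodeInputs(
            np.hstack([latent[0], rng.standard_normal((n_d, 2))]),
            rng.standard_normal((n_d, 4)),
            np.hstack([latent[1], rng.standard_normal((n_t, 2))]),
            rng.standard_normal((n_t, 4)),
        )
        return pairs, inputs

    def test_overfits_linearly_separable_toy(self):
        pairs, inputs = self._separable_setup()
        split = {"train": pairs.iloc[:30], "val": pairs.iloc[30:33],
                 "test": pairs.iloc[33:]}
        g = build_graph(split, sorted(pairs.drug_id.unique()),
                        sorted(pairs.target_id.unique()))
        cfg = toy_config(latent=8, hidden1=8, hidden2=8, max_epochs=200,
                         patience=200, lr=3e-3)
        model, history = train_model(g, inputs, cfg)
        assert history["train_loss"].min() < 0.05

    def test_same_seed_identical_history(self):
        pairs, inputs = self._separable_setup()
        split = {"train": pairs.iloc[:30], "val": pairs.iloc[30:33],
                 "test": pairs.iloc[33:]}
        g = build_graph(split, sorted(pairs.drug_id.unique()),
                        sorted(pairs.target_id.unique()))
        cfg = toy_config(dropout=0.3, use_batchnorm=True, max_epochs=8, patience=8)
        _, h1 = train_model(g, inputs, cfg)
        _, h2 = train_model(g, inputs, cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_train_split_rejected(self):
        g = build_graph({"train": pairs_df([("d1", "t1", 1)])})
        g.supervision["train"] = g.supervision["train"][:0]
        with pytest.raises(ValueError):
            train_model(g, toy_inputs(1, 1), toy_config())

    def test_restores_best_checkpoint(self):
        pairs, inputs = self._separable_setup()
        split = {"train": pairs.iloc[:30], "val": pairs.iloc[30:33],
                 "test": pairs.iloc[33:]}
        g = build_graph(split, sorted(pairs.drug_id.unique()),
                        sorted(pairs.target_id.unique()))
        cfg = toy_config(max_epochs=60, patience=5)
        model, history = train_model(g, inputs, cfg)
        val = g.supervision["val"]
        from topolink.graph import _bce_from_logits
        restored = _bce_from_logits(model.pair_logits(inputs, g, val).data,
                                    val[:, 2])
        assert restored == pytest.approx(history["val_loss"].min(), abs=1e-9)
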