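import numpy as np
import pytest

import pathprime as pp
from pathprime.network import apply_activation, cross_entropy


class TestActivations:
    def test_fixed_points(self):
        assert apply_activation(np.array([0.0]), "tanh")[0] == 0.0
        assert apply_activation(np.array([-3.0]), "relu")[0] == 0.0
        assert apply_activation(np.array([0.0]), "sigmoid")[0] == 0.5

    def test_softmax_symmetry(self):
        np.testing.assert_allclose(
            apply_activation(np.array([0.0, 0.0]), "softmax"), [0.5, 0.5]
        )

    def test_softmax_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        direct = np.exp(x) / np.exp(x).sum()
        np.testing.assert_allclose(
            apply_activation(x, "softmax"), direct, atol=1e-12
        )

    def test_softmax_max_shift_stability(self):
        out = apply_activation(np.array([1000.0, 1000.0]), "softmax")
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_tanh_matches_exponential_form(self):
        x = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(
            apply_activation(x, "tanh"),
            (1 - np.exp(-2 * x)) / (1 + np.exp(-2 * x)),
            atol=1e-12,
        )


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_over_four_classes(self):
        y = np.array([[1.0, 0, 0, 0]])
        p = np.full((1, 4), 0.25)
        assert cross_entropy(y, p) == pytest.approx(np.log(4))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=8)
        y = np.eye(3)[rng.integers(0, 3, 8)]
        perm = rng.permutation(8)
        assert cross_entropy(y, p) == pytest.approx(cross_entropy(y[perm], p[perm]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 3)), np.ones((2, 2)))


def _mask(genes, sets):
    coll = pp.GeneSetCollection(
        [(f"S{i}", "", frozenset(s)) for i, s in enumerate(sets)]
    )
    return pp.build_mask(genes, coll)


class TestBuildNetwork:
    def test_seeded_builds_are_identical(self):
        cfg = pp.NetworkConfig(
            input_genes=["g1", "g2", "g3"],
            hidden_layers=[pp.LayerSpec(dense_nodes=4)],
            n_classes=2,
            seed=9,
        )
        a, b = pp.build_network(cfg), pp.build_network(cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert (wa == wb).all()

    def test_free_weight_count_matches_mask(self):
        genes = ["g1", "g2", "g3"]
        mask = _mask(genes, [{"g1", "g2"}, {"g3"}])
        cfg = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=2,
            seed=0,
        )
        model = pp.build_network(cfg, mask)
        assert (model.weights[0] != 0).sum() == 3

    def test_all_ones_mask_equals_dense_init(self):
        genes = [f"g{i}" for i in range(5)]
        ones = pp.PriorMask(np.ones((5, 3)), genes, ["a", "b", "c"])
        cfg_m = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=2,
            seed=4,
        )
        cfg_d = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(dense_nodes=3)],
            n_classes=2,
            seed=4,
        )
        m = pp.build_network(cfg_m, ones)
        d = pp.build_network(cfg_d)
        for wm, wd in zip(m.weights, d.weights):
            assert (wm == wd).all()

    def test_mask_gene_order_mismatch_rejected(self):
        genes = ["g1", "g2"]
        mask = _mask(["g2", "g1"], [{"g1"}])
        cfg = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=2,
            seed=0,
        )
        with pytest.raises(ValueError, match="gene order"):
            pp.build_network(cfg, mask)

    def test_only_first_layer_may_be_biological(self):
        with pytest.raises(ValueError):
            pp.NetworkConfig(
                input_genes=["g1"],
                hidden_layers=[
                    pp.LayerSpec(dense_nodes=2),
                    pp.LayerSpec(biological=True),
                ],
                n_classes=2,
            )


class TestCountEffectiveParameters:
    def test_mouse_dense_architecture(self):
        # 9437 input genes, one hidden layer of 100, 16 cell-type outputs
        cfg = pp.NetworkConfig(
            input_genes=[f"g{i}" for i in range(9437)],
            hidden_layers=[pp.LayerSpec(dense_nodes=100)],
            n_classes=16,
        )
        assert pp.count_effective_parameters(cfg) == 945_416

    def test_all_ones_mask_equals_dense_count(self):
        genes = [f"g{i}" for i in range(7)]
        ones = pp.PriorMask(np.ones((7, 4)), genes, list("abcd"))
        cfg_m = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=3,
        )
        cfg_d = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(dense_nodes=4)],
            n_classes=3,
        )
        assert pp.count_effective_parameters(
            cfg_m, ones
        ) == pp.count_effective_parameters(cfg_d)

    def test_small_masked_example(self):
        # 4 genes, sets {g1,g2},{g3}: 3 free weights + 2 biases + 2x2 output + 2
        genes = ["g1", "g2", "g3", "g4"]
        mask = _mask(genes, [{"g1", "g2"}, {"g3"}])
        cfg = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=2,
        )
        assert pp.count_effective_parameters(cfg, mask) == 11

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_genes = int(rng.integers(3, 12))
            n_nodes = int(rng.integers(1, 5))
            n_classes = int(rng.integers(2, 5))
            matrix = np.zeros((n_genes, n_nodes))
            while (matrix.sum(axis=0) == 0).any():
                matrix = (rng.random((n_genes, n_nodes)) < 0.5).astype(float)
            genes = [f"g{i}" for i in range(n_genes)]
            mask = pp.PriorMask(matrix, genes, [f"n{j}" for j in range(n_nodes)])
            dense_extra = int(rng.integers(0, 3))
            cfg = pp.NetworkConfig(
                input_genes=genes,
                hidden_layers=[
                    pp.LayerSpec(biological=True, dense_nodes=dense_extra)
                ],
                n_classes=n_classes,
            )
            model = pp.build_network(cfg, mask)
            # brute force: count allowed positions + biases across all layers
            expected = int(model.first_layer_mask.sum())
            expected += model.weights[0].shape[1]
            for w, b in zip(model.weights[1:], model.biases[1:]):
                expected += w.size + b.size
            assert pp.count_effective_parameters(cfg, mask) == expected


class TestTraining:
    def test_separable_toy_learns_perfectly(self, separable_toy):
        X, y = separable_toy
        Xp, _ = pp.preprocess(X, "zscore")
        cfg = pp.NetworkConfig(
            input_genes=X.gene_ids,
            hidden_layers=[pp.LayerSpec(dense_nodes=4)],
            n_classes=2,
            seed=1,
        )
        model = pp.build_network(cfg)
        pp.train(model, Xp, y, pp.TrainingConfig(epochs=10, seed=1))
        losses = model.history
        assert all(b < a for a, b in zip(losses[:5], losses[1:6]))
        assert pp.supervised_metrics(y, pp.predict(model, Xp)).accuracy == 1.0

    def test_masked_weights_stay_zero_every_step(self, tiny_masked):
        Xb, y, collb, mask, _ = tiny_masked
        Xp, _ = pp.preprocess(Xb, "zscore")
        cfg = pp.NetworkConfig(
            input_genes=Xb.gene_ids,
            hidden_layers=[pp.LayerSpec(biological=True, dense_nodes=2)],
            n_classes=y.n_classes,
            seed=3,
        )
        model = pp.build_network(cfg, mask)
        worst = []
        pp.train(
            model,
            Xp,
            y,
            pp.TrainingConfig(epochs=2, seed=3),
            callback=lambda step, m: worst.append(
                np.abs(m.weights[0][m.first_layer_mask == 0]).max()
            ),
        )
        assert max(worst) == 0.0
        assert np.abs(model.weights[0][model.first_layer_mask == 0]).max() == 0.0

    @pytest.mark.parametrize("optimizer", ["sgd", "adam"])
    def test_training_is_deterministic(self, separable_toy, optimizer):
        X, y = separable_toy
        Xp, _ = pp.preprocess(X, "zscore")

        def run():
            cfg = pp.NetworkConfig(
                input_genes=X.gene_ids,
                hidden_layers=[pp.LayerSpec(dense_nodes=3)],
                n_classes=2,
                seed=2,
            )
            model = pp.build_network(cfg)
            tcfg = pp.default_training_config(optimizer, epochs=4, seed=2)
            pp.train(model, Xp, y, tcfg)
            return model

        a, b = run(), run()
        for wa, wb in zip(a.weights, b.weights):
            assert (wa == wb).all()

    def test_all_ones_mask_training_matches_dense_trajectory(self, separable_toy):
        X, y = separable_toy
        Xp, _ = pp.preprocess(X, "zscore")
        genes = X.gene_ids
        ones = pp.PriorMask(np.ones((4, 3)), genes, ["a", "b", "c"])
        cfg_m = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(biological=True)],
            n_classes=2,
            seed=6,
        )
        cfg_d = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(dense_nodes=3)],
            n_classes=2,
            seed=6,
        )
        m = pp.build_network(cfg_m, ones)
        d = pp.build_network(cfg_d)
        tcfg = pp.TrainingConfig(epochs=3, seed=6)
        pp.train(m, Xp, y, tcfg)
        pp.train(d, Xp, y, tcfg)
        for wm, wd in zip(m.weights, d.weights):
            np.testing.assert_allclose(wm, wd, atol=1e-6)

    def test_unseen_class_count_rejected(self, separable_toy):
        X, y3 = separable_toy[0], pp.LabelVector(["A"] * 7 + ["B"] * 7 + ["C"] * 6)
        cfg = pp.NetworkConfig(
            input_genes=X.gene_ids,
            hidden_layers=[pp.LayerSpec(dense_nodes=3)],
            n_classes=2,
            seed=0,
        )
        model = pp.build_network(cfg)
        with pytest.raises(ValueError, match="classes"):
            pp.train(model, X, y3, pp.TrainingConfig(epochs=1))


class TestPrediction:
    def test_rows_sum_to_one(self, trained_tiny):
        model, Xp, y = trained_tiny
        out = pp.predict_proba(model, Xp)
        np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert (out.probabilities >= 0).all()

    def test_matches_manual_forward_pass(self, trained_tiny):
        model, Xp, y = trained_tiny
        x = Xp.values
        for w, b in zip(model.weights[:-1], model.biases[:-1]):
            x = np.tanh(x @ w + b)
        logits = x @ model.weights[-1] + model.biases[-1]
        manual = np.exp(logits - logits.max(axis=1, keepdims=True))
        manual /= manual.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            pp.predict_proba(model, Xp).probabilities, manual, atol=1e-6
        )

    def test_biased_degenerate_model_always_picks_class_zero(self):
        genes = ["g1", "g2"]
        cfg = pp.NetworkConfig(
            input_genes=genes,
            hidden_layers=[pp.LayerSpec(dense_nodes=2)],
            n_classes=2,
            seed=0,
        )
        model = pp.build_network(cfg)
        model.class_order = ["A", "B"]
        model.biases[-1] = np.array([50.0, -50.0])
        X = pp.ExpressionMatrix(np.random.default_rng(0).normal(size=(5, 2)), genes, list("abcde"))
        assert pp.predict(model, X) == ["A"] * 5

    def test_gene_mismatch_lists_offenders(self, trained_tiny):
        model, Xp, _ = trained_tiny
        bad = pp.ExpressionMatrix(
            Xp.values[:, :3], ["x1", "x2", "x3"], Xp.cell_ids
        )
        with pytest.raises(ValueError, match="x1"):
            pp.predict_proba(model, bad)


class TestSerialization:
    def test_save_load_round_trip(self, trained_tiny, tmp_path):
        model, Xp, _ = trained_tiny
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = pp.TrainedModel.load(path)
        for wa, wb in zip(model.weights, loaded.weights):
            assert (wa == wb).all()
        assert loaded.class_order == model.class_order
        assert loaded.biological_node_names == model.biological_node_names
        np.testing.assert_allclose(
            pp.predict_proba(loaded, Xp).probabilities,
            pp.predict_proba(model, Xp).probabilities,
        )
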