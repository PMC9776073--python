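import numpy as np
import pytest

from gcfusion.fusionnet import (
    FusionError,
    FusionGCN,
    ModelConfig,
    ablate,
    cross_validate,
    paired_ttest,
)
from gcfusion.pipeline import GraphDataset


def _toy_dataset(n_samples=24, n_channels=4, seed=0, identical_bands=False):
    rng = np.random.default_rng(seed)
    nodes = rng.normal(size=(n_samples, 4, n_channels))
    adj = (rng.random((n_samples, 4, n_channels, n_channels)) < 0.5).astype(float)
    adj[..., np.arange(n_channels), np.arange(n_channels)] = 1.0
    if identical_bands:
        nodes = np.repeat(nodes[:, :1], 4, axis=1)
        adj = np.repeat(adj[:, :1], 4, axis=1)
    labels = np.arange(n_samples) % 2
    return GraphDataset(nodes, adj, labels)


def _tiny_config(**kw):
    base = dict(d1=3, d2=3, fc1_dim=4, cheb_K=2, epochs=2, batch_size=8, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestForward:
    def test_softmax_output_sums_to_one(self):
        model = FusionGCN(_toy_dataset(), _tiny_config())
        params = model.init_params(np.random.default_rng(0))
        probs, _ = model.forward(params, model.prepare_inputs())
        assert probs.shape == (24, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs >= 0)

    def test_identical_bands_make_output_independent_of_fusion_weights(self):
        model = FusionGCN(_toy_dataset(identical_bands=True), _tiny_config())
        rng = np.random.default_rng(0)
        params = model.init_params(rng)
        # identical per-band convolution parameters, arbitrary fusion logits
        for key in ("thetaS", "WS", "thetaD", "WD"):
            params[key][:] = params[key][:1]
        inputs = model.prepare_inputs()
        probs_a, _ = model.forward(params, inputs)
        params["qS"] = rng.normal(size=4)
        params["qD"] = rng.normal(size=4)
        probs_b, _ = model.forward(params, inputs)
        assert np.allclose(probs_a, probs_b, atol=1e-12)

    def test_one_hot_fusion_weight_selects_single_band(self):
        model = FusionGCN(_toy_dataset(), _tiny_config())
        params = model.init_params(np.random.default_rng(1))
        params["qS"] = np.array([0.0, 0.0, 60.0, 0.0])  # p_beta -> 1
        _, cache = model.forward(params, model.prepare_inputs())
        assert np.allclose(cache["XFS"], cache["XS"][:, 2], atol=1e-12)

    def test_wrong_band_count_rejected_for_fused_variant(self):
        ds = _toy_dataset()
        ds3 = GraphDataset(ds.node_values[:, :3], ds.adjacency[:, :3], ds.labels, ("a", "b", "c"))
        with pytest.raises(FusionError, match="4 bands"):
            FusionGCN(ds3, _tiny_config(fusion="fused"))
        FusionGCN(ds3, _tiny_config(fusion="cascade"))  # cascade accepts any band count

    def test_node_permutation_invariance_with_consistent_reordering(self):
        """Permuting nodes everywhere (features, adjacency, dense input
        ordering) leaves the class probabilities unchanged."""
        ds = _toy_dataset()
        cfg = _tiny_config(standardize=False)
        model = FusionGCN(ds, cfg)
        params = model.init_params(np.random.default_rng(2))
        probs, _ = model.forward(params, model.prepare_inputs())

        n, d1, d2 = ds.n_channels, cfg.d1, cfg.d2
        perm = np.random.default_rng(3).permutation(n)
        ds_p = GraphDataset(
            ds.node_values[:, :, perm],
            ds.adjacency[:, :, perm][:, :, :, perm],
            ds.labels,
        )
        model_p = FusionGCN(ds_p, cfg)
        params_p = {k: v.copy() for k, v in params.items()}
        params_p["W1S"] = params["W1S"].reshape(n, d1, -1)[perm].reshape(n * d1, -1)
        params_p["W1D"] = params["W1D"].reshape(n, d2, -1)[perm].reshape(n * d2, -1)
        probs_p, _ = model_p.forward(params_p, model_p.prepare_inputs())
        assert np.allclose(probs, probs_p, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize(
        "depth,fusion,per_node",
        [
            ("both", "fused", False),
            ("both", "fused", True),
            ("both", "cascade", False),
            ("shallow", "fused", False),
            ("deep", "fused", False),
        ],
    )
    def test_analytic_gradients_match_finite_differences(self, depth, fusion, per_node):
        model = FusionGCN(
            _toy_dataset(n_samples=6, n_channels=3),
            _tiny_config(depth=depth, fusion=fusion, per_node_fusion=per_node),
        )
        rng = np.random.default_rng(0)
        params = model.init_params(rng)
        for key in params:
            params[key] = params[key] + rng.normal(0, 0.1, params[key].shape)
        inputs = model.prepare_inputs()
        _, grads = model.loss_and_grads(params, inputs)
        eps = 1e-6
        for key, p in params.items():
            flat = p.ravel()
            for i in range(0, flat.size, max(1, flat.size // 5)):  # spot-check entries
                orig = flat[i]
                flat[i] = orig + eps
                lp = model.loss(params, inputs)
                flat[i] = orig - eps
                lm = model.loss(params, inputs)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[i] == pytest.approx(num, abs=1e-4)


class TestTraining:
    def test_same_seed_gives_identical_weights(self, small_dataset):
        cfg = ModelConfig(epochs=2, seed=11)
        res_a = FusionGCN(small_dataset, cfg).fit()
        res_b = FusionGCN(small_dataset, cfg).fit()
        for key in res_a.params:
            assert np.array_equal(res_a.params[key], res_b.params[key])
        assert np.array_equal(res_a.loss_history, res_b.loss_history)

    def test_simplex_preserved_after_every_step(self, small_dataset):
        res = FusionGCN(small_dataset, ModelConfig(epochs=5, seed=0)).fit()
        assert len(res.weight_history) > 0
        for snap in res.weight_history:
            for p in snap.values():
                assert np.all(p >= 0)
                assert np.sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_loss_decreases_on_separable_task(self, small_dataset):
        res = FusionGCN(small_dataset, ModelConfig(epochs=30, seed=0)).fit()
        assert res.loss_history[-1] < res.loss_history[0]

    def test_summary_reports_weights_and_accuracy(self, fitted_small_model):
        _, res = fitted_small_model
        text = res.summary()
        assert "fusion weights" in text and "accuracy" in text
        assert res.n_params == sum(p.size for p in res.params.values())

    def test_checkpoint_round_trip(self, fitted_small_model, tmp_path):
        model, res = fitted_small_model
        path = tmp_path / "ckpt.npz"
        res.save(path)
        restored = type(res).load(path, model)
        assert np.array_equal(restored.predict(), res.predict())
        for key in res.params:
            assert np.array_equal(restored.params[key], res.params[key])

    def test_shuffled_labels_score_at_chance(self, small_dataset):
        rng = np.random.default_rng(0)
        shuffled = GraphDataset(
            small_dataset.node_values,
            small_dataset.adjacency,
            rng.permutation(small_dataset.labels),
            small_dataset.band_ids,
        )
        rep = cross_validate(shuffled, ModelConfig(epochs=30, seed=0), n_folds=5, seed=0)
        spread = max(3 * rep.std, 20.0)  # 3 sd of the fold accuracies
        assert abs(rep.mean - 50.0) <= spread


class TestCrossValidation:
    def test_folds_partition_segments(self, small_dataset):
        rep = cross_validate(small_dataset, ModelConfig(epochs=2, seed=0), n_folds=5, seed=1)
        all_idx = np.concatenate(rep.fold_test_indices)
        assert len(all_idx) == len(small_dataset)
        assert len(np.unique(all_idx)) == len(small_dataset)
        sizes = [len(ix) for ix in rep.fold_test_indices]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_fold_assignment(self, small_dataset):
        rep_a = cross_validate(small_dataset, ModelConfig(epochs=1, seed=0), seed=9)
        rep_b = cross_validate(small_dataset, ModelConfig(epochs=1, seed=0), seed=9)
        for ia, ib in zip(rep_a.fold_test_indices, rep_b.fold_test_indices):
            assert np.array_equal(ia, ib)

    def test_separable_task_scores_high(self, small_dataset):
        rep = cross_validate(small_dataset, ModelConfig(epochs=60, seed=0), n_folds=5, seed=0)
        assert rep.mean >= 80.0
        assert rep.confusion.sum() == len(small_dataset)

    def test_too_few_segments_per_class_rejected(self):
        ds = _toy_dataset(n_samples=6)
        with pytest.raises(FusionError):
            cross_validate(ds, _tiny_config(), n_folds=5)


class TestAblate:
    def test_one_row_per_variant(self, small_dataset):
        variants = (
            ("shallow-fused", "shallow", "fused"),
            ("shallow-cascade", "shallow", "cascade"),
        )
        table = ablate(
            small_dataset,
            ModelConfig(epochs=2, seed=0),
            variants=variants,
            n_folds=3,
            seed=0,
        )
        assert list(table["variant"]) == ["shallow-fused", "shallow-cascade"]
        assert {"mean", "std", "accuracy"} <= set(table.columns)


class TestPairedTTest:
    def test_identical_vectors_flagged_degenerate(self):
        with pytest.raises(FusionError, match="zero-variance"):
            paired_ttest([90.0, 91.0, 92.0], [90.0, 91.0, 92.0])

    def test_consistent_offset_highly_significant(self):
        # ~5-point advantage on every fold (an exactly constant offset has
        # zero-variance differences and is rejected as degenerate)
        b = np.array([88.0, 90.5, 91.0, 89.2, 92.3])
        offset = 5.0 + np.array([0.1, -0.2, 0.15, -0.05, 0.0])
        p = paired_ttest(b + offset, b)
        assert p < 0.01

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(90, 3, size=(2, 6))
        assert paired_ttest(a, b) == pytest.approx(paired_ttest(b, a))

    def test_known_t_distribution_value(self):
        # differences exactly [1, 2, 3, 4, 5]: t = 3/sqrt(2.5/5), df = 4
        from scipy import stats

        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(5)
        t = 3.0 / np.sqrt(2.5 / 5)
        expected = 2 * stats.t.sf(t, df=4)
        assert paired_ttest(a, b) == pytest.approx(expected, rel=1e-12)
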