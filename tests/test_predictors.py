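import numpy as np
import pytest
from scipy.stats import spearmanr

from methactivity.io_formats import ExpressionMatrix
from methactivity.predictors import (
    EnsembleModel,
    TrainedModel,
    feature_importance,
    load_bundle,
    predict,
    save_bundle,
    subsample_training_pairs,
    train_cnn,
    train_elastic_net,
    train_ensemble,
    train_random_forest,
)


def random_design(rng, n=400, p=40):
    return rng.random((n, p))


@pytest.fixture(scope="module")
def planted():
    """X with y depending only on meth_rate bins 11-12 (columns 30, 31).

    The cpg channel carries a smooth positional profile peaking at the TSS,
    as real promoter CpG densities do; this is what lets a conv + max-pool
    network localize specific bins (bins are not identifiable from an
    exchangeable i.i.d. input).
    """
    rng = np.random.default_rng(42)
    pos = np.arange(20)
    profile = 0.1 + 0.5 * np.exp(-((pos - 9.5) ** 2) / 8.0)
    cpg = profile[None, :] * rng.uniform(0.5, 1.5, size=(3000, 1)) + 0.02 * rng.random(
        (3000, 20)
    )
    mr = rng.random((3000, 20))
    X = np.hstack([cpg, mr])
    y = 0.5 * (mr[:, 10] + mr[:, 11])
    return X, y


class TestSubsample:
    def _tensor_and_targets(self, n_genes=5, n_cells=6, seed=0):
        from methactivity.features import FeatureTensor

        rng = np.random.default_rng(seed)
        pg = np.repeat(np.arange(n_genes), n_cells)
        pc = np.tile(np.arange(n_cells), n_genes)
        tensor = FeatureTensor(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            cell_ids=[f"c{i}" for i in range(n_cells)],
            pair_gene_idx=pg,
            pair_cell_idx=pc,
            cpg_ratio=rng.random((n_genes * n_cells, 20)),
            meth_rate=rng.random((n_genes * n_cells, 20)),
            meth_mask=np.zeros((n_genes * n_cells, 20), dtype=bool),
        )
        targets = ExpressionMatrix(
            genes=tensor.gene_ids,
            cells=tensor.cell_ids,
            values=rng.random((n_genes, n_cells)),
        )
        return tensor, targets

    def test_clamp_returns_all_in_order(self):
        tensor, targets = self._tensor_and_targets()
        X, y = subsample_training_pairs(tensor, targets, n=10_000, seed=1)
        assert len(y) == 30
        np.testing.assert_allclose(X, tensor.X)

    def test_same_seed_identical(self):
        tensor, targets = self._tensor_and_targets(10, 10)
        a = subsample_training_pairs(tensor, targets, n=20, seed=5)
        b = subsample_training_pairs(tensor, targets, n=20, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_pairs_without_expression_excluded(self):
        tensor, targets = self._tensor_and_targets()
        reduced = ExpressionMatrix(
            genes=targets.genes[:3], cells=targets.cells, values=targets.values[:3]
        )
        X, y = subsample_training_pairs(tensor, reduced, n=10_000, seed=0)
        assert len(y) == 3 * 6

    def test_no_eligible_pairs_error(self):
        tensor, targets = self._tensor_and_targets()
        empty = ExpressionMatrix(genes=["zz"], cells=["qq"], values=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            subsample_training_pairs(tensor, empty)

    def test_default_matches_published_setting(self):
        import inspect

        sig = inspect.signature(subsample_training_pairs)
        assert sig.parameters["n"].default == 100_000


class TestRandomForest:
    def test_constant_target(self, rng):
        X = random_design(rng, n=50)
        with pytest.warns(UserWarning):
            model = train_random_forest(X, np.full(50, 0.3), n_trees=10, seed=0)
        np.testing.assert_allclose(model.predict(X), 0.3)

    def test_learns_single_feature(self, rng):
        X = random_design(rng, n=500)
        y = X[:, 7]
        model = train_random_forest(X, y, n_trees=100, seed=0)
        pred = model.predict(X)
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95

    def test_defaults_match_published(self):
        import inspect

        sig = inspect.signature(train_random_forest)
        assert sig.parameters["n_trees"].default == 500
        assert sig.parameters["sample_frac"].default == 0.8

    def test_bit_reproducible(self, rng):
        X = random_design(rng, n=200)
        y = rng.random(200)
        p1 = train_random_forest(X, y, n_trees=20, seed=9).predict(X)
        p2 = train_random_forest(X, y, n_trees=20, seed=9).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestElasticNet:
    def test_recovers_coefficient(self, rng):
        X = random_design(rng, n=300)
        y = 2.0 * X[:, 0]
        model = train_elastic_net(X, y, seed=0)
        coef = model.model["coef"]
        assert abs(coef[0] - 2.0) / 2.0 < 0.05
        assert np.all(np.abs(np.delete(coef, 0)) < 0.05)

    def test_strong_penalty_limit_predicts_mean(self, rng):
        # tiny sample with pure noise: CV should pick heavy shrinkage;
        # check the limit behaviour via a hand-set huge penalty instead
        from sklearn.linear_model import ElasticNet

        X = random_design(rng, n=60)
        y = rng.random(60)
        enet = ElasticNet(alpha=1e6, l1_ratio=0.5).fit(X, y)
        np.testing.assert_allclose(enet.coef_, 0.0)
        assert enet.intercept_ == pytest.approx(y.mean())

    def test_defaults_match_published(self):
        import inspect

        sig = inspect.signature(train_elastic_net)
        assert sig.parameters["alpha_mix"].default == 0.5
        assert sig.parameters["n_cv_folds"].default == 10

    def test_too_few_samples_error(self, rng):
        with pytest.raises(ValueError):
            train_elastic_net(random_design(rng, n=5), np.ones(5))

    def test_bit_reproducible(self, rng):
        X = random_design(rng, n=100)
        y = X[:, 0] + 0.1 * rng.random(100)
        m1 = train_elastic_net(X, y, seed=3)
        m2 = train_elastic_net(X, y, seed=3)
        np.testing.assert_array_equal(m1.model["coef"], m2.model["coef"])


class TestCnn:
    def test_constant_target(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 40))
        y = np.full(200, 0.4)
        model = train_cnn(X, y, seed=0, max_epochs=30)
        pred = model.predict(X)
        assert np.mean((pred - 0.4) ** 2) <= 0.01

    def test_planted_signal_learnable(self, planted):
        X, y = planted
        model = train_cnn(X[:2500], y[:2500], seed=1, max_epochs=100)
        rho = spearmanr(model.predict(X[2500:]), y[2500:]).statistic
        assert rho > 0.9

    def test_defaults_match_published(self):
        import inspect

        sig = inspect.signature(train_cnn)
        assert sig.parameters["n_filters"].default == 50
        assert sig.parameters["kernel"].default == 5
        assert sig.parameters["pool"].default == 4
        assert sig.parameters["dropout"].default == 0.2
        assert sig.parameters["patience"].default == 10

    def test_reproducible_within_tolerance(self):
        rng = np.random.default_rng(5)
        X = rng.random((300, 40))
        y = X[:, 25] + 0.05 * rng.random(300)
        p1 = train_cnn(X, y, seed=11, max_epochs=15).predict(X)
        p2 = train_cnn(X, y, seed=11, max_epochs=15).predict(X)
        np.testing.assert_allclose(p1, p2, atol=1e-5)


def _fake_component(offset, feature_order=None):
    class _Const:
        def __init__(self, off):
            self.off = off

        def predict(self, X):
            return np.full(X.shape[0], self.off)

    comp = TrainedModel(
        model_kind="random_forest",
        model=_Const(offset),
        feature_order=feature_order or [f"f{i}" for i in range(4)],
    )
    return comp


class TestEnsembleRules:
    def test_unweighted_is_mean(self):
        ens = EnsembleModel(components=[_fake_component(v) for v in (0.2, 0.4, 0.6)])
        X = np.zeros((3, 4))
        np.testing.assert_allclose(ens.predict(X), 0.4)

    def test_identical_components_pass_through(self, rng):
        comps = [_fake_component(0.37) for _ in range(3)]
        for rule, kwargs in [
            ("unweighted", {}),
            ("weighted_correlation", {"weights": np.array([0.5, 0.3, 0.2])}),
        ]:
            ens = EnsembleModel(components=comps, rule=rule, **kwargs)
            np.testing.assert_allclose(ens.predict(np.zeros((5, 4))), 0.37)

    def test_weighted_dot_product(self):
        comps = [_fake_component(v) for v in (1.0, 0.0, 0.0)]
        ens = EnsembleModel(
            components=comps,
            rule="weighted_correlation",
            weights=np.array([0.5, 0.3, 0.2]),
        )
        np.testing.assert_allclose(ens.predict(np.zeros((2, 4))), 0.5)

    def test_unweighted_bounded_by_components(self, rng):
        X = rng.random((50, 40))
        y = X[:, 0]
        ens = train_ensemble(
            X,
            y,
            rule="unweighted",
            seed=0,
            component_params={
                "random_forest": {"n_trees": 5},
                "elastic_net": {"n_cv_folds": 3},
                "cnn": {"max_epochs": 3},
            },
        )
        outs = ens.component_outputs(X)
        pred = ens.predict(X)
        assert np.all(pred <= outs.max(axis=1) + 1e-12)
        assert np.all(pred >= outs.min(axis=1) - 1e-12)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            EnsembleModel(
                components=[_fake_component(0.1)],
                rule="weighted_correlation",
                weights=np.array([0.5, 0.6]),
            )
        with pytest.raises(ValueError):
            EnsembleModel(components=[_fake_component(0.1)], rule="stacking")

    @pytest.mark.parametrize("rule", ["weighted_correlation", "weighted_accuracy", "stacking"])
    def test_trainable_rules(self, rng, rule):
        X = rng.random((120, 40))
        y = X[:, 30] + 0.1 * rng.random(120)
        ens = train_ensemble(
            X,
            y,
            rule=rule,
            seed=1,
            cv_folds=3,
            component_params={
                "random_forest": {"n_trees": 5},
                "elastic_net": {"n_cv_folds": 3},
                "cnn": {"max_epochs": 3},
            },
        )
        pred = ens.predict(X)
        assert np.all(np.isfinite(pred))
        if rule.startswith("weighted"):
            assert ens.weights.sum() == pytest.approx(1.0)
            assert np.all(ens.weights >= 0)


class TestFeatureImportance:
    def test_constant_feature_zero_importance(self, rng):
        X = random_design(rng, n=300)
        X[:, 5] = 0.5
        y = X[:, 0]
        model = train_random_forest(X, y, n_trees=30, seed=0)
        scores = feature_importance(model, X, y, n_repeats=3, seed=0)
        assert scores[5] == 0.0

    def test_planted_feature_ranks_first(self, rng):
        X = random_design(rng, n=600)
        y = X[:, 30]  # meth_rate bin 11
        model = train_random_forest(X, y, n_trees=80, seed=0)
        scores = feature_importance(model, X, y, n_repeats=3, seed=0)
        assert np.argmax(scores) == 30

    def test_noise_features_near_zero(self, rng):
        X = random_design(rng, n=400)
        y = X[:, 0]
        model = train_random_forest(X, y, n_trees=50, seed=0)
        scores = feature_importance(model, X, y, n_repeats=5, seed=0)
        assert np.all(np.abs(scores[1:]) < 0.5 * scores[0])


class TestBundleRoundTrip:
    def test_save_load_predict_identical(self, rng, tmp_path):
        X = rng.random((150, 40))
        y = X[:, 30] + 0.2 * X[:, 5]
        ens = train_ensemble(
            X,
            y,
            rule="unweighted",
            seed=2,
            component_params={
                "random_forest": {"n_trees": 10},
                "elastic_net": {"n_cv_folds": 3},
                "cnn": {"max_epochs": 5},
            },
        )
        before = ens.predict(X)
        save_bundle(ens, tmp_path / "bundle", extra_meta={"note": "test"})
        loaded = load_bundle(tmp_path / "bundle")
        after = loaded.predict(X)
        np.testing.assert_allclose(after, before, atol=1e-6)
        assert loaded.rule == "unweighted"
        assert loaded.feature_order == ens.feature_order

    def test_layout_mismatch_rejected(self, rng, tmp_path):
        X = rng.random((60, 40))
        model = train_random_forest(X, X[:, 0], n_trees=3, seed=0)
        with pytest.raises(ValueError, match="layout"):
            model.predict(rng.random((5, 10)))


def test_predict_rejects_nonfinite(rng):
    class _Bad:
        def predict(self, X):
            return np.full(X.shape[0], np.nan)

    model = TrainedModel(
        model_kind="random_forest", model=_Bad(), feature_order=[f"f{i}" for i in range(4)]
    )
    with pytest.raises(FloatingPointError):
        predict(model, rng.random((3, 4)))
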