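import numpy as np
import pytest
from scipy.stats import pearsonr

from pathdrp import (
    FeatureTable,
    HyperParams,
    group_holdout_split,
    group_kfold,
    load_ensemble,
    predict,
    save_ensemble,
    train_baseline,
    train_classifier,
    train_ensemble,
    train_regressor,
    tune_hyperparameters,
)
from pathdrp.model import (
    DROPOUT_GRID,
    LAYER_GRID,
    LR_GRID,
    WIDTH_GRID,
    _MLP,
    _val_loss,
    sample_candidates,
)

from conftest import make_feature_table

HP_FAST = HyperParams(n_hidden_extra=2, width=128, dropout=0.1, lr=1e-3)


def linear_table(n=2000, F=30, noise=0.1, seed=0, n_drugs=5):
    """Planted linear signal y = w.x + noise over group-structured keys."""
    rng = np.random.default_rng(seed)
    n_samples = n // n_drugs
    keys = [(f"S{i}", f"D{j}") for i in range(n_samples) for j in range(n_drugs)]
    X = rng.standard_normal((len(keys), F))
    w = rng.standard_normal(F) / np.sqrt(F)
    y = X @ w + rng.normal(0, noise, len(keys))
    P = F // 2
    return FeatureTable(keys=keys, X=X, y=y,
                        pathway_names=[f"P{i}" for i in range(P)],
                        drug_dims=[f"d{i}" for i in range(F - P)]), w


class TestArchitecture:
    def test_weight_layer_shapes(self):
        F = 37
        for L in (2, 4, 6):
            hp = HyperParams(n_hidden_extra=L, width=132, dropout=0.2, lr=1e-4)
            net = _MLP(F, hp, "regression", seed=0)
            shapes = net.weight_shapes()
            assert len(shapes) == L + 2
            assert shapes[0] == (F, 512)
            assert shapes[1] == (512, 132)
            assert shapes[2:-1] == [(132, 132)] * (L - 1)
            assert shapes[-1] == (132, 1)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            HyperParams(n_hidden_extra=1, width=128, dropout=0.1, lr=1e-3)
        with pytest.raises(ValueError):
            HyperParams(n_hidden_extra=2, width=130, dropout=0.1, lr=1e-3)
        with pytest.raises(ValueError):
            HyperParams(n_hidden_extra=2, width=128, dropout=0.6, lr=1e-3)
        with pytest.raises(ValueError):
            HyperParams(n_hidden_extra=2, width=128, dropout=0.1, lr=1e-2)


class TestTrainRegressor:
    def test_constant_target_fit(self):
        # enough rows that 50 epochs give the optimizer a few thousand steps
        t = make_feature_table(n_samples=1000, n_drugs=5, P=6, E=4, seed=1)
        c = 3.0
        t = FeatureTable(keys=t.keys, X=t.X, y=np.full(len(t), c),
                         pathway_names=t.pathway_names, drug_dims=t.drug_dims)
        m = train_regressor(t, HP_FAST, seed=0)
        assert np.all(np.abs(m.predict(t.X) - c) <= 0.05 * (1 + abs(c)))

    def test_planted_linear_signal_recovered(self):
        t, _ = linear_table(seed=3)
        plan = group_holdout_split(t, frac=0.9, seed=3)
        m = train_regressor(t, HP_FAST, seed=0, rows=plan.train_rows(t))
        test = t.subset(plan.test_rows(t))
        rho = pearsonr(m.predict(test.X), test.y).statistic
        assert rho >= 0.9

    def test_permuted_labels_give_null_correlation(self):
        t, _ = linear_table(seed=4)
        rng = np.random.default_rng(0)
        t_perm = FeatureTable(keys=t.keys, X=t.X, y=rng.permutation(t.y),
                              pathway_names=t.pathway_names, drug_dims=t.drug_dims)
        plan = group_holdout_split(t_perm, frac=0.9, seed=4)
        m = train_regressor(t_perm, HP_FAST, seed=0, rows=plan.train_rows(t_perm))
        test = t_perm.subset(plan.test_rows(t_perm))
        rho = pearsonr(m.predict(test.X), test.y).statistic
        assert abs(rho) <= 0.15

    def test_reproducible_from_seed(self):
        t = make_feature_table(n_samples=30, n_drugs=4, seed=5)
        m1 = train_regressor(t, HP_FAST, seed=9)
        m2 = train_regressor(t, HP_FAST, seed=9)
        assert np.array_equal(m1.predict(t.X), m2.predict(t.X))


class TestClassifier:
    def _separable_table(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = n // 4
        keys = [(f"S{i}", f"D{j}") for i in range(n_samples) for j in range(4)]
        X = rng.standard_normal((len(keys), 12))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        return FeatureTable(keys=keys, X=X, y=y,
                            pathway_names=[f"P{i}" for i in range(8)],
                            drug_dims=[f"d{i}" for i in range(4)],
                            task="classification")

    def test_outputs_are_probabilities(self):
        t = self._separable_table(200)
        m = train_classifier(t, HP_FAST, seed=0, epochs=5)
        p = m.predict(t.X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_separable_classes_high_auc_pr(self):
        from pathdrp import classification_metrics
        t = self._separable_table(1000, seed=2)
        plan = group_holdout_split(t, frac=0.9, seed=2)
        m = train_classifier(t, HP_FAST, seed=0, rows=plan.train_rows(t))
        test = t.subset(plan.test_rows(t))
        out = classification_metrics(m.predict(test.X), test.y)
        assert out["auc_pr"] >= 0.95

    def test_shuffled_labels_null_auc(self):
        from pathdrp import classification_metrics
        rng = np.random.default_rng(1)
        t = self._separable_table(1000, seed=3)
        t_perm = FeatureTable(keys=t.keys, X=t.X, y=rng.permutation(t.y),
                              pathway_names=t.pathway_names,
                              drug_dims=t.drug_dims, task="classification")
        plan = group_holdout_split(t_perm, frac=0.9, seed=3)
        m = train_classifier(t_perm, HP_FAST, seed=0, rows=plan.train_rows(t_perm))
        test = t_perm.subset(plan.test_rows(t_perm))
        out = classification_metrics(m.predict(test.X), test.y)
        assert out["auc"] == pytest.approx(0.5, abs=0.07)

    def test_single_class_errors(self):
        t = self._separable_table(100)
        t_bad = FeatureTable(keys=t.keys, X=t.X, y=np.ones(len(t)),
                             pathway_names=t.pathway_names,
                             drug_dims=t.drug_dims, task="classification")
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(t_bad, HP_FAST, seed=0)


class TestTuning:
    def test_budget_one_forces_the_single_candidate(self):
        t = make_feature_table(n_samples=20, n_drugs=3, seed=6)
        plan = group_kfold(group_holdout_split(t, seed=6), k=3, seed=6)
        chosen = tune_hyperparameters(plan, t, budget=1, seed=42)
        expected = sample_candidates(np.random.default_rng(42), 1)[0]
        assert chosen == [expected] * 3

    def test_choice_always_within_grids(self):
        t = make_feature_table(n_samples=20, n_drugs=3, seed=7)
        plan = group_kfold(group_holdout_split(t, seed=7), k=2, seed=7)
        for hp in tune_hyperparameters(plan, t, budget=3, seed=1):
            assert hp.n_hidden_extra in LAYER_GRID
            assert hp.width in WIDTH_GRID
            assert hp.dropout in DROPOUT_GRID
            assert hp.lr in LR_GRID

    def test_chosen_config_not_worse_than_median_candidate(self):
        t, _ = linear_table(n=600, F=12, noise=0.1, seed=8)
        plan = group_kfold(group_holdout_split(t, seed=8), k=2, seed=8)
        budget, seed = 3, 5
        chosen = tune_hyperparameters(plan, t, budget=budget, seed=seed)
        candidates = sample_candidates(np.random.default_rng(seed), budget)
        for fi, (tr_g, va_g) in enumerate(plan.cv_folds):
            tr = plan.rows_for_groups(t, tr_g)
            va = plan.rows_for_groups(t, va_g)
            losses = [_val_loss(t, hp, tr, va, seed * 1009 + fi,
                                hp.epochs_tune, t.task) for hp in candidates]
            chosen_loss = losses[candidates.index(chosen[fi])]
            assert chosen_loss <= np.median(losses)


class TestEnsemble:
    def test_k1_equals_single_model(self):
        t = make_feature_table(n_samples=20, n_drugs=3, seed=9)
        e = train_ensemble(t, [HP_FAST], seed=3)
        member, mean = predict(e, t.X)
        assert np.array_equal(member[0], mean)

    def test_mean_is_member_average_and_deterministic(self):
        t = make_feature_table(n_samples=20, n_drugs=3, seed=10)
        e = train_ensemble(t, [HP_FAST] * 3, seed=4)
        X2 = np.vstack([t.X, t.X])  # duplicated rows -> identical predictions
        member, mean = predict(e, X2)
        assert member.shape == (3, 2 * len(t))
        assert np.allclose(mean, member.mean(axis=0), atol=1e-12)
        assert np.array_equal(mean[:len(t)], mean[len(t):])

    def test_member_predictions_reported_per_row(self):
        t = make_feature_table(n_samples=10, n_drugs=2, seed=11)
        e = train_ensemble(t, [HP_FAST] * 5, seed=5)
        member, _ = predict(e, t.X[:4])
        assert member.shape == (5, 4)  # 5 values for every (sample, drug) row

    def test_schema_aware_column_realignment(self):
        t = make_feature_table(n_samples=15, n_drugs=3, seed=12)
        e = train_ensemble(t, [HP_FAST], seed=6)
        perm = np.random.default_rng(0).permutation(t.F)
        cols = [t.column_names[i] for i in perm]
        _, mean_perm = predict(e, t.X[:, perm], columns=cols)
        _, mean = predict(e, t.X)
        assert np.array_equal(mean, mean_perm)

    def test_width_mismatch_names_problem(self):
        t = make_feature_table(n_samples=10, n_drugs=2, seed=13)
        e = train_ensemble(t, [HP_FAST], seed=7)
        with pytest.raises(ValueError, match="width"):
            predict(e, t.X[:, :-1])
        with pytest.raises(ValueError, match="missing"):
            predict(e, t.X, columns=["bogus"] + t.column_names[1:])

    def test_save_load_round_trip(self, tmp_path):
        t = make_feature_table(n_samples=12, n_drugs=2, seed=14)
        e = train_ensemble(t, [HP_FAST] * 2, seed=8)
        save_ensemble(e, tmp_path / "bundle")
        back = load_ensemble(tmp_path / "bundle")
        _, m1 = predict(e, t.X)
        _, m2 = predict(back, t.X)
        assert np.array_equal(m1, m2)


class TestBaselines:
    def test_elasticnet_recovers_planted_linear(self):
        t, _ = linear_table(n=600, F=15, noise=0.1, seed=15)
        plan = group_kfold(group_holdout_split(t, seed=15), k=3, seed=15)
        models, chosen = train_baseline("elasticnet", t, plan, seed=0, n_boot=5)
        test = t.subset(plan.test_rows(t))
        preds = np.mean([m.predict(test.X) for m in models], axis=0)
        assert pearsonr(preds, test.y).statistic >= 0.9
        assert len(models) == len(plan.cv_folds)

    def test_rf_selection_is_argmin_on_fold(self):
        t, _ = linear_table(n=300, F=10, noise=0.3, seed=16)
        plan = group_kfold(group_holdout_split(t, seed=16), k=2, seed=16)
        mtry_grid, tree_grid = (2, 5), (50, 100)
        models, chosen = train_baseline("rf", t, plan, seed=1,
                                        rf_mtry_grid=mtry_grid,
                                        rf_tree_grid=tree_grid)
        from sklearn.ensemble import RandomForestRegressor
        for fi, (tr_g, va_g) in enumerate(plan.cv_folds):
            tr = t.subset(plan.rows_for_groups(t, tr_g))
            va = t.subset(plan.rows_for_groups(t, va_g))
            losses = {}
            for mtry in mtry_grid:
                for n_trees in tree_grid:
                    rf = RandomForestRegressor(n_estimators=n_trees,
                                               max_features=mtry,
                                               random_state=1 * 1009 + fi,
                                               n_jobs=1)
                    rf.fit(tr.X, tr.y)
                    losses[(mtry, n_trees)] = np.mean((rf.predict(va.X) - va.y) ** 2)
            best = min(losses, key=losses.get)
            assert (chosen[fi]["mtry"], chosen[fi]["n_trees"]) == best
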