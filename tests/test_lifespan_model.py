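import numpy as np
import pandas as pd
import pytest

from finlife.feature_table import FeatureTable
from finlife.lifespan_model import (
    BaggedModel,
    ElasticNetComponent,
    build_lambda_path,
    fit_component,
    inner_cv_select,
    predict,
    select_lambda_1se,
    stratified_split,
    train_bagged,
)
from finlife.synthetic_data import SimulationConfig, simulate_study

PIDS3 = ["P1", "P2", "P3"]


class TestStratifiedSplit:
    def test_70_30_counts_with_10_bins(self, rng):
        y = rng.normal(size=100)
        tr, te = stratified_split(y, 0.7, 10, seed=1)
        assert (len(tr), len(te)) == (70, 30)
        assert sorted(np.concatenate([tr, te])) == list(range(100))

    def test_single_bin_simple_split(self, rng):
        tr, te = stratified_split(rng.normal(size=10), 0.7, 1, seed=1)
        assert (len(tr), len(te)) == (7, 3)

    def test_each_percentile_bin_contributes_to_both_sets(self, rng):
        y = np.sort(rng.normal(size=100))
        tr, _ = stratified_split(y, 0.7, 10, seed=3)
        for lo in range(0, 100, 10):  # y sorted, so bins are index ranges
            in_bin = np.sum((tr >= lo) & (tr < lo + 10))
            assert in_bin == 7

    def test_determinism_contract(self, rng):
        y = rng.normal(size=50)
        a = stratified_split(y, 0.7, 5, seed=9)
        b = stratified_split(y, 0.7, 5, seed=9)
        c = stratified_split(y, 0.7, 5, seed=10)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])

    def test_too_many_bins_rejected(self, rng):
        with pytest.raises(ValueError, match="n_bins"):
            stratified_split(rng.normal(size=5), 0.7, 10, seed=0)


class TestLambdaSelection:
    def test_1se_rule_on_hand_computed_curve(self):
        # minimum 0.85 at lambda 2, SE 0.1 -> threshold 0.95 -> largest is 5
        lambdas = np.array([10, 5, 2, 1, 0.5])
        errors = np.array([1.0, 0.9, 0.85, 0.9, 1.0])
        assert select_lambda_1se(lambdas, errors, 0.1) == 5.0

    def test_se_array_indexed_at_minimum(self):
        lambdas = np.array([10, 5, 2, 1, 0.5])
        errors = np.array([1.0, 0.9, 0.85, 0.9, 1.0])
        se = np.array([9.0, 9.0, 0.1, 9.0, 9.0])
        assert select_lambda_1se(lambdas, errors, se) == 5.0

    def test_zero_se_returns_the_minimizer(self):
        lambdas = np.array([4.0, 2.0, 1.0])
        errors = np.array([3.0, 1.0, 2.0])
        assert select_lambda_1se(lambdas, errors, 0.0) == 2.0

    def test_path_is_descending_and_spans_expected_ratio(self, rng):
        X = rng.normal(size=(50, 10))
        Xs = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=50)
        path = build_lambda_path(Xs, y - y.mean(), alpha=0.5, n_lambda=100)
        assert len(path) == 100
        assert np.all(np.diff(path) < 0)
        assert path[-1] / path[0] == pytest.approx(1e-2)  # n >= p
        path_wide = build_lambda_path(Xs[:5], (y - y.mean())[:5], 0.5)
        assert path_wide[-1] / path_wide[0] == pytest.approx(1e-4)  # n < p


class TestInnerCvSelect:
    def test_grid_of_one_alpha_returned(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ [1, -1, 0, 0, 0.5] + rng.normal(scale=0.3, size=40)
        alpha, lam, curve = inner_cv_select(X, y, alpha_grid=[0.343], seed=0)
        assert alpha == 0.343
        assert lam >= curve.loc[curve.mean_cv_error.idxmin(), "lambda"]

    def test_degenerate_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            inner_cv_select(rng.normal(size=(20, 3)), np.ones(20), seed=0)

    def test_lambda_1se_at_least_lambda_min_error(self, rng):
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.5, size=60)
        _, lam, curve = inner_cv_select(X, y, alpha_grid=[0.125, 1.0], seed=1)
        assert lam >= curve.loc[curve.mean_cv_error.idxmin(), "lambda"]


class TestFitComponent:
    def test_full_shrinkage_limit(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        comp = fit_component(X, y, alpha=1.0, lambda_1se=1e6, promoter_ids=list("abcd"))
        assert comp.coefficients == {}
        assert comp.intercept == pytest.approx(y.mean())

    def test_ridge_closed_form_agreement(self, rng):
        """At alpha=0 the solver must match the normal-equations solution
        (X'X + n*lambda*I)^-1 X'y computed on the standardized scale."""
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        lam = 0.05
        comp = fit_component(X, y, alpha=0.0, lambda_1se=lam, promoter_ids=PIDS3)
        Xs = (X - X.mean(0)) / X.std(0)
        b_std = np.linalg.solve(Xs.T @ Xs + 5 * lam * np.eye(3), Xs.T @ (y - y.mean()))
        b = b_std / X.std(0)
        b0 = y.mean() - b @ X.mean(0)
        got = np.array([comp.coefficients.get(p, 0.0) for p in PIDS3])
        np.testing.assert_allclose(got, b, atol=1e-5)
        assert comp.intercept == pytest.approx(b0, abs=1e-5)

    def test_duplicated_feature_splits_ridge_weight(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, 0.5, -0.8] + rng.normal(scale=0.2, size=60)
        lam = 1e-3
        single = fit_component(X, y, 0.0, lam, PIDS3)
        Xdup = np.column_stack([X, X[:, 0]])
        dup = fit_component(Xdup, y, 0.0, lam, PIDS3 + ["P1b"])
        b1, b1b = dup.coefficients["P1"], dup.coefficients["P1b"]
        assert b1 == pytest.approx(b1b, rel=1e-2)
        assert b1 + b1b == pytest.approx(single.coefficients["P1"], rel=0.05)

    def test_constant_feature_gets_zero_coefficient(self, rng):
        X = np.column_stack([rng.normal(size=30), np.full(30, 7.0)])
        y = X[:, 0] * 2 + rng.normal(scale=0.1, size=30)
        comp = fit_component(X, y, 0.5, 0.01, ["P1", "Pconst"])
        assert comp.coefficients.get("Pconst", 0.0) == 0.0

    def test_non_finite_input_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="finite"):
            fit_component(X, np.array([1.0, 2.0]), 0.5, 0.1, ["a", "b"])

    def test_nonzero_count_monotone_along_lambda_path(self, rng):
        """Lasso sparsity grows with the penalty (up to solver tolerance)."""
        X = rng.normal(size=(50, 20))
        y = X @ np.r_[np.ones(5), np.zeros(15)] + rng.normal(scale=0.5, size=50)
        Xs = (X - X.mean(0)) / X.std(0)
        path = build_lambda_path(Xs, y - y.mean(), 1.0, 50)
        from finlife.lifespan_model import _fit_path

        coefs = _fit_path(Xs, y - y.mean(), 1.0, path)
        nnz = (np.abs(coefs) > 1e-8).sum(axis=1)  # descending lambda order
        assert np.all(np.diff(nnz) >= -1)  # non-decreasing, 1-feature slack


class TestPredict:
    def component(self, intercept=1.0, coefs=None):
        coefs = coefs or {}
        return ElasticNetComponent(
            alpha=0.5,
            lambda_1se=0.1,
            intercept=intercept,
            coefficients=coefs,
            feature_means={},
            feature_sds={},
        )

    def test_identical_components_equal_single(self):
        comp = self.component(intercept=2.0, coefs={"P1": 0.5})
        model = BaggedModel(components=[comp] * 10, promoter_ids=PIDS3)
        X = np.array([[1.0, 0.0, 0.0]])
        single = BaggedModel(components=[comp], promoter_ids=PIDS3)
        np.testing.assert_allclose(predict(model, X), predict(single, X))

    def test_all_zero_row_closed_form(self):
        comps = [self.component(intercept=b0) for b0 in (1.0, 2.0, 3.0)]
        model = BaggedModel(components=comps, promoter_ids=PIDS3)
        np.testing.assert_allclose(
            predict(model, np.zeros((1, 3))), [np.exp(2.0)]
        )

    def test_predictions_positive_and_column_order_invariant(self, rng):
        comps = [self.component(0.5, {"P1": 0.3, "P3": -0.2})]
        model = BaggedModel(components=comps, promoter_ids=PIDS3)
        df = pd.DataFrame(rng.uniform(0, 2, size=(4, 3)), columns=PIDS3)
        shuffled = df[["P3", "P1", "P2"]]
        np.testing.assert_allclose(predict(model, df), predict(model, shuffled))
        assert np.all(predict(model, df) > 0)

    def test_missing_columns_filled_extra_rejected(self):
        model = BaggedModel(
            components=[self.component(1.0, {"P1": 1.0})], promoter_ids=PIDS3
        )
        partial = pd.DataFrame({"P1": [2.0]})  # P2, P3 -> 0
        np.testing.assert_allclose(predict(model, partial), [np.exp(3.0)])
        with pytest.raises(ValueError, match="unknown"):
            predict(model, pd.DataFrame({"P1": [1.0], "PX": [1.0]}))


class TestTrainBagged:
    def small_table(self, rng, n=40, p=6):
        X = rng.uniform(0, 2, size=(n, p))
        y = np.exp(1.5 + X @ np.r_[0.8, -0.6, np.zeros(p - 2)]
                   + rng.normal(scale=0.3, size=n))
        return FeatureTable(
            species_ids=[f"s{i}" for i in range(n)],
            promoter_ids=[f"P{i}" for i in range(p)],
            matrix=X,
            known_lifespan=y,
        )

    def test_too_few_species_advises(self, rng):
        with pytest.raises(ValueError, match="at least 30"):
            train_bagged(self.small_table(rng, n=10), seed=0)

    def test_single_outer_fold(self, rng):
        model, report = train_bagged(
            self.small_table(rng), n_outer=1, alpha_grid=[0.125], n_lambda=30,
            n_inner_folds=5, seed=0,
        )
        assert len(model.components) == 1 and len(report) == 1

    def test_same_seed_bit_identical(self, rng):
        table = self.small_table(rng)
        kwargs = dict(n_outer=2, alpha_grid=[0.0, 1.0], n_lambda=30,
                      n_inner_folds=5)
        m1, _ = train_bagged(table, seed=5, **kwargs)
        m2, _ = train_bagged(table, seed=5, **kwargs)
        for c1, c2 in zip(m1.components, m2.components):
            assert c1.coefficients == c2.coefficients
            assert c1.intercept == c2.intercept

    def test_dense_signal_selects_ridge_like_alpha(self):
        """With every promoter causal, inner CV should land near the ridge
        end of the grid in every outer fold."""
        config = SimulationConfig(n_species=80, n_promoters=40, n_causal=40, seed=3)
        study = simulate_study(config)
        _, report = train_bagged(study.feature_table(), seed=3)
        assert len(report) == 10
        assert (report.alpha <= 0.1).all()


def test_model_json_round_trip(tmp_path, rng):
    X = rng.uniform(0, 2, size=(40, 4))
    y = np.exp(1.0 + X[:, 0] + rng.normal(scale=0.2, size=40))
    table = FeatureTable(
        species_ids=[f"s{i}" for i in range(40)],
        promoter_ids=[f"P{i}" for i in range(4)],
        matrix=X,
        known_lifespan=y,
    )
    model, _ = train_bagged(table, n_outer=2, alpha_grid=[0.5], n_lambda=20,
                            n_inner_folds=5, seed=1)
    model.to_json(tmp_path / "m.json")
    back = BaggedModel.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(predict(back, table), predict(model, table))
    assert back.promoter_ids == model.promoter_ids
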