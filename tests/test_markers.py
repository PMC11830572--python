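import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from portal5hmc.markers import (ClassifierModel, SplitSpec, _class_weights,
                                cv_score, fit_penalized_logistic,
                                panel_from_rounds, rfe, split_cohort,
                                stability_select, standardize,
                                train_final_model)


def sample_table(n_a, n_b, labels=("PC", "MLM")):
    ids = [f"{labels[0]}_{i:03d}" for i in range(n_a)] + \
        [f"{labels[1]}_{i:03d}" for i in range(n_b)]
    return pd.DataFrame({"group": [labels[0]] * n_a + [labels[1]] * n_b},
                        index=pd.Index(ids, name="sample"))


def planted_data(n=120, p=20, n_informative=2, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i:02d}" for i in range(p)],
                     index=[f"s{i:03d}" for i in range(n)])
    y = (rng.random(n) < 0.5).astype(float)
    for j in range(n_informative):
        X.iloc[:, j] += sep * (1 if j % 2 == 0 else -1) * y
    return X, pd.Series(y, index=X.index)


class TestSplitCohort:
    def test_exact_arithmetic_small(self):
        train, valid = split_cohort(sample_table(6, 3), SplitSpec(seed=1))
        tg = [t.split("_")[0] for t in train]
        vg = [v.split("_")[0] for v in valid]
        assert (tg.count("PC"), tg.count("MLM")) == (4, 2)
        assert (vg.count("PC"), vg.count("MLM")) == (2, 1)

    def test_cohort_scale_round_half_even(self):
        train, valid = split_cohort(sample_table(70, 32), SplitSpec(seed=2))
        tg = [t.split("_")[0] for t in train]
        assert (tg.count("PC"), tg.count("MLM")) == (47, 21)
        assert len(train) + len(valid) == 102
        assert set(train).isdisjoint(valid)

    def test_deterministic_given_seed(self):
        spec = SplitSpec(seed=7)
        assert split_cohort(sample_table(20, 10), spec) == \
            split_cohort(sample_table(20, 10), spec)

    def test_empty_validation_class_errors(self):
        with pytest.raises(ValueError):
            split_cohort(sample_table(6, 3), SplitSpec(train_fraction=0.99))


class TestPenalizedLogistic:
    def test_huge_lambda_shrinks_weights(self):
        X, y = planted_data(seed=3)
        Z, _, _ = standardize(X)
        m = fit_penalized_logistic(Z, y.to_numpy(), lam=1e6)
        assert np.linalg.norm(m.weights) < 1e-3

    def test_balanced_weights_unit_when_classes_equal(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        assert np.allclose(_class_weights(y, "balanced"), 1.0)
        y2 = np.array([0, 0, 0, 1], dtype=float)
        assert np.allclose(_class_weights(y2, "balanced"), [2 / 3, 2 / 3, 2 / 3, 2.0])

    def test_two_point_problem_matches_grid_oracle(self):
        # one feature, two points; profile out the intercept (0 by symmetry)
        X = pd.DataFrame({"f": [-1.0, 1.0]})
        y = np.array([0.0, 1.0])
        lam = 1.0

        def obj(b):
            eta = np.array([-b, b])
            return float(np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * lam * b * b)

        oracle = minimize_scalar(obj, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12})
        m = fit_penalized_logistic(X, y, lam=lam)
        assert m.weights[0] == pytest.approx(oracle.x, abs=1e-5)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import LogisticRegression

        X, y = planted_data(n=80, p=6, seed=5)
        Z, _, _ = standardize(X)
        for lam in (0.1, 1.0, 10.0):
            m = fit_penalized_logistic(Z, y.to_numpy(), lam=lam)
            sk = LogisticRegression(C=1 / lam, class_weight="balanced",
                                    solver="lbfgs", tol=1e-12, max_iter=10000
                                    ).fit(Z.to_numpy(), y.to_numpy())
            assert np.allclose(m.weights, sk.coef_[0], atol=1e-5)
            assert m.intercept == pytest.approx(sk.intercept_[0], abs=1e-5)

    def test_constant_labels_error(self):
        X, _ = planted_data(n=10, seed=6)
        with pytest.raises(ValueError, match="constant label"):
            fit_penalized_logistic(X, np.ones(10), lam=1.0)


class TestCvScore:
    def test_separable_data_perfect_accuracy(self):
        X, y = planted_data(n=60, p=4, sep=8.0, seed=8)
        Z, _, _ = standardize(X)
        best, scores = cv_score(Z.to_numpy(), y.to_numpy(), seed=1)
        assert max(scores.values()) == 1.0

    def test_single_lambda_returned(self):
        X, y = planted_data(n=40, p=3, seed=9)
        best, scores = cv_score(X.to_numpy(), y.to_numpy(), lambda_grid=(3.5,))
        assert best == 3.5 and list(scores) == [3.5]

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(400, 5))
        y = (rng.random(400) < 0.5).astype(float)
        _, scores = cv_score(X, y, seed=2)
        assert abs(max(scores.values()) - max(y.mean(), 1 - y.mean())) < 0.12

    def test_tie_prefers_larger_lambda(self):
        X, y = planted_data(n=60, p=2, sep=8.0, seed=11)
        Z, _, _ = standardize(X)
        best, scores = cv_score(Z.to_numpy(), y.to_numpy(),
                                lambda_grid=(0.01, 0.1, 1.0), seed=3)
        tied = [l for l, s in scores.items() if s == max(scores.values())]
        assert best == max(tied)


class TestRfe:
    def test_single_feature_selected(self):
        X, y = planted_data(n=40, p=1, n_informative=1, seed=12)
        res = rfe(X, y.to_numpy(), seed=1)
        assert res.selected_ids == ["f00"]

    def test_recovers_planted_features_across_seeds(self):
        hits = 0
        X, y = planted_data(n=200, p=50, n_informative=2, sep=2.0, seed=13)
        Z, _, _ = standardize(X)
        for s in range(100):
            res = rfe(Z, y.to_numpy(), lambda_grid=(0.01, 1.0, 100.0), seed=s)
            hits += {"f00", "f01"} <= set(res.selected_ids)
        assert hits >= 95

    def test_duplicated_feature_does_not_grow_selection(self):
        X, y = planted_data(n=80, p=5, n_informative=1, sep=4.0, seed=14)
        X["f00_copy"] = X["f00"]
        Z, _, _ = standardize(X)
        res = rfe(Z, y.to_numpy(), seed=4)
        assert len(res.selected_ids) <= X.shape[1]
        assert {"f00", "f00_copy"} & set(res.selected_ids)

    def test_deterministic(self):
        X, y = planted_data(n=60, p=10, seed=15)
        a = rfe(X, y.to_numpy(), seed=9)
        b = rfe(X, y.to_numpy(), seed=9)
        assert a.selected_ids == b.selected_ids
        assert a.accuracy_by_size == b.accuracy_by_size


class TestStabilitySelect:
    def test_consensus_rule(self):
        rounds = pd.Series({"a": 3, "b": 2, "c": 5, "d": 0})
        assert panel_from_rounds(rounds, 3) == ["a", "c"]
        assert panel_from_rounds(rounds, 1) == ["a", "b", "c"]

    def test_perfect_predictor_all_rounds(self):
        X, y = planted_data(n=60, p=6, n_informative=1, sep=10.0, seed=16)
        panel = stability_select(X, y, n_repeats=10, seed=5,
                                 lambda_grid=(0.01, 1.0, 100.0))
        assert "f00" in panel.marker_ids
        assert panel.rounds_observed["f00"] == 5
        assert np.allclose(panel.frequencies.loc["f00"], 1.0)

    def test_deterministic_given_seed(self):
        X, y = planted_data(n=50, p=8, seed=17)
        a = stability_select(X, y, n_repeats=5, seed=6, lambda_grid=(1.0,))
        b = stability_select(X, y, n_repeats=5, seed=6, lambda_grid=(1.0,))
        assert a.marker_ids == b.marker_ids
        pd.testing.assert_frame_equal(a.frequencies, b.frequencies)

    def test_panel_shrinks_with_min_rounds(self):
        X, y = planted_data(n=60, p=10, n_informative=3, sep=1.5, seed=18)
        panel = stability_select(X, y, n_repeats=10, seed=7,
                                 lambda_grid=(0.01, 1.0, 100.0))
        sizes = [len(panel_from_rounds(panel.rounds_observed, k))
                 for k in range(1, 6)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestFinalModel:
    def test_probabilities_monotone_in_single_marker(self):
        X, y = planted_data(n=80, p=1, n_informative=1, sep=3.0, seed=19)
        model = train_final_model(X, y.to_numpy(), seed=1)
        grid = pd.DataFrame({"f00": np.linspace(-3, 3, 25)})
        probs = model.predict_proba(grid)
        assert np.all(np.diff(probs) >= 0)

    def test_refit_identical_with_seed(self):
        X, y = planted_data(n=60, p=4, seed=20)
        a = train_final_model(X, y.to_numpy(), seed=3)
        b = train_final_model(X, y.to_numpy(), seed=3)
        assert a.to_json() == b.to_json()

    def test_standardization_frozen_from_training_only(self):
        # leakage check: permuting validation rows leaves the model unchanged
        X, y = planted_data(n=90, p=5, seed=21)
        train = X.index[:60]
        valid = X.index[60:]
        model = train_final_model(X.loc[train], y.loc[train].to_numpy(), seed=2)
        before = model.to_json()
        scores = model.predict_proba(X.loc[valid])
        perm = np.random.default_rng(0).permutation(len(valid))
        scores_perm = model.predict_proba(X.loc[valid[perm]])
        assert model.to_json() == before
        assert np.allclose(np.sort(scores), np.sort(scores_perm))

    def test_json_roundtrip(self):
        X, y = planted_data(n=40, p=3, seed=22)
        model = train_final_model(X, y.to_numpy(), seed=4)
        back = ClassifierModel.from_json(model.to_json())
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))
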