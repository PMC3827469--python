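"""Nuclear Score learning: IRLS, CV objective, SFFS, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nucleomorph import synthetic
from nucleomorph.scoring import (
    SingularDesignError,
    fit_irls,
    objective_J,
    predict_ns,
    sffs_select,
    single_feature_rescore,
    train_score_model,
)


class Data:
    """Minimal TrainingSet-shaped container."""

    def __init__(self, X, y, names=None):
        names = names or [f"f{i}" for i in range(X.shape[1])]
        self.features = pd.DataFrame(X, columns=names)
        self.scores = pd.Series(np.asarray(y, dtype=float), name="human_ns")


class TestFitIrls:
    def test_exact_linear_data_recovered_to_1e8(self):
        ts = synthetic.make_training_set(80, [5.0, 0.5, -0.4, 0.3], seed=1)
        res = fit_irls(ts.features.to_numpy(), ts.scores.to_numpy())
        assert np.abs(res.theta - ts.theta_true).max() < 1e-8

    def test_constant_response_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        res = fit_irls(X, np.full(40, 4.2))
        assert res.theta[0] == pytest.approx(4.2, abs=1e-10)
        assert np.abs(res.theta[1:]).max() < 1e-10

    @pytest.mark.parametrize("weight_function", ["huber", "bisquare", "cauchy"])
    def test_outlier_resistance_beats_ols(self, weight_function):
        wins = 0
        for seed in range(25):
            ts = synthetic.make_training_set(
                200, [5.5, 0.8, -0.6, 0.7], outlier_fraction=0.1, noise_sd=0.5,
                seed=seed)
            X = ts.features.to_numpy()
            y = ts.scores.to_numpy()
            rob = fit_irls(X, y, weight_function=weight_function)
            ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)
            err_rob = np.linalg.norm(rob.theta - ts.theta_true)
            err_ols = np.linalg.norm(ols - ts.theta_true)
            wins += err_rob < err_ols
        assert wins >= 23

    def test_matches_statsmodels_rlm_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        ts = synthetic.make_training_set(150, [5.0, 0.9, -0.5], outlier_fraction=0.08,
                                         noise_sd=0.4, seed=3)
        X = ts.features.to_numpy()
        y = ts.scores.to_numpy()
        ours = fit_irls(X, y, weight_function="huber")
        rlm = sm.RLM(y, sm.add_constant(X), M=sm.robust.norms.HuberT()).fit()
        np.testing.assert_allclose(ours.theta, rlm.params, atol=0.02)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0]])  # duplicate column
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_irls(X, rng.standard_normal(30), column_names=["a", "b", "a_copy"])

    def test_parameter_recovery_with_gaussian_noise(self):
        # 5% relative error across seeds with sd-0.5 noise, no outliers
        for seed in range(10):
            ts = synthetic.make_training_set(500, [5.5, 1.2, -0.9, 0.8], noise_sd=0.5,
                                             seed=seed)
            res = fit_irls(ts.features.to_numpy(), ts.scores.to_numpy())
            rel = np.linalg.norm(res.theta - ts.theta_true) / np.linalg.norm(ts.theta_true)
            assert rel < 0.05


class TestObjectiveJ:
    def test_leaked_response_gives_tiny_error(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 10, 60)
        X = np.column_stack([y, rng.standard_normal(60)])
        d = Data(X, y, names=["leak", "noise"])
        assert objective_J(["leak"], d, seed=0) < 0.01

    def test_pure_noise_near_intercept_only_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(1, 10, 400)
        X = rng.standard_normal((400, 3))
        d = Data(X, y)
        j = objective_J(["f0", "f1", "f2"], d, seed=2)
        oracle = np.abs(y - np.median(y)).mean()
        assert abs(j - oracle) / oracle < 0.20

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        d = Data(rng.standard_normal((50, 4)), rng.uniform(1, 10, 50))
        assert objective_J(["f1", "f3"], d, seed=5) == objective_J(["f1", "f3"], d, seed=5)

    def test_rank_deficient_subset_returns_inf(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 2))
        X = np.column_stack([X, np.zeros(40)])
        d = Data(X, rng.uniform(1, 10, 40), names=["a", "b", "flat"])
        with pytest.warns(UserWarning, match="excluded"):
            assert objective_J(["a", "flat"], d, seed=0) == np.inf


class TestSffs:
    def test_matches_exhaustive_search_on_planted_instances(self):
        ok = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            names = [f"f{i}" for i in range(8)]
            X = rng.standard_normal((80, 8))
            theta = np.zeros(8)
            idx = rng.choice(8, 3, replace=False)
            theta[idx] = rng.uniform(0.8, 1.5, 3) * rng.choice([-1, 1], 3)
            y = np.clip(5 + X @ theta + 0.3 * rng.standard_normal(80), 1, 10)
            d = Data(X, y, names)
            trace = sffs_select(names, d, k_max=4, seed=seed)
            good = True
            for k in (2, 3, 4):
                best = min(
                    objective_J(list(c), d, seed=seed)
                    for c in itertools.combinations(names, k)
                )
                if abs(trace.entries[k][1] - best) > 1e-9:
                    good = False
            ok += good
        assert ok >= 7  # SFFS is a heuristic; near-universal optimality expected

    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 10, 60)
        X = np.column_stack([rng.standard_normal((60, 2)), y, rng.standard_normal(60)])
        d = Data(X, y, names=["n1", "n2", "perfect", "n3"])
        trace = sffs_select(["n1", "n2", "perfect", "n3"], d, k_max=2, seed=0)
        assert "perfect" in trace.entries[2][0]

    def test_constructed_redundancy_triggers_floating_removal(self):
        # y = a + b exactly; c = a + b + noise is individually best but must be
        # floated out once {a, b} is complete
        rng = np.random.default_rng(3)
        a = rng.standard_normal(80)
        b = rng.standard_normal(80)
        y = np.clip(5 + a + b, 1, 10)
        c = a + b + 0.4 * rng.standard_normal(80)
        noise = rng.standard_normal((80, 3))
        X = np.column_stack([a, b, c, noise])
        names = ["a", "b", "c", "n1", "n2", "n3"]
        d = Data(X, y, names)
        trace = sffs_select(names, d, k_max=4, seed=0)
        assert trace.n_floating_removals >= 1
        assert set(trace.entries[2][0]) == {"a", "b"}

    def test_records_exactly_one_subset_per_size(self):
        rng = np.random.default_rng(6)
        d = Data(rng.standard_normal((60, 6)), rng.uniform(1, 10, 60))
        trace = sffs_select(list(d.features.columns), d, k_max=5, seed=1)
        assert sorted(trace.entries) == [2, 3, 4, 5]


class TestTrainScoreModel:
    def test_auto_k_finds_informative_subset_size(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p, inf = 200, 23, 12
            X = rng.standard_normal((n, p))
            theta = np.zeros(p)
            theta[:inf] = rng.uniform(0.6, 1.3, inf) * rng.choice([-1, 1], inf)
            y = np.clip(5.5 + X @ theta + 0.6 * rng.standard_normal(n), 1, 10)
            d = Data(X, y, names=list(synthetic.FEATURE_NAMES))
            model, trace = train_score_model(d, k="auto", k_max=16, seed=seed)
            if abs(len(model.selected_features) - inf) <= 2:
                hits += 1
        assert hits >= 8

    def test_forced_k_gives_k_plus_one_coefficients(self):
        rng = np.random.default_rng(0)
        d = Data(rng.standard_normal((60, 5)), rng.uniform(1, 10, 60))
        model, _ = train_score_model(d, k=2, seed=0)
        assert len(model.theta) == 3
        assert len(model.selected_features) == 2

    def test_retrain_identical(self):
        rng = np.random.default_rng(9)
        d = Data(rng.standard_normal((60, 5)), rng.uniform(1, 10, 60))
        m1, _ = train_score_model(d, k=3, seed=4)
        m2, _ = train_score_model(d, k=3, seed=4)
        assert m1.selected_features == m2.selected_features
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_model_json_round_trip(self):
        from nucleomorph.scoring import ScoreModel

        rng = np.random.default_rng(2)
        d = Data(rng.standard_normal((50, 4)), rng.uniform(1, 10, 50))
        model, _ = train_score_model(d, k=2, seed=1)
        clone = ScoreModel.from_json(model.to_json())
        assert clone.selected_features == model.selected_features
        np.testing.assert_array_equal(clone.theta, model.theta)


class TestPredictNs:
    @pytest.fixture()
    def model(self):
        ts = synthetic.make_training_set(100, [5.0, 2.0, -1.5], seed=0)
        d = Data(ts.features.to_numpy(), ts.scores.to_numpy(),
                 names=list(ts.features.columns))
        model, _ = train_score_model(d, k=2, seed=0)
        return model, ts

    def test_clamped_to_range(self, model):
        m, ts = model
        extreme = {f: 100.0 for f in m.selected_features}
        assert predict_ns(m, extreme) == 10.0
        extreme = {f: -100.0 for f in m.selected_features}
        assert predict_ns(m, extreme) == 1.0

    def test_noiseless_training_rows_reproduced(self, model):
        m, ts = model
        pred = predict_ns(m, ts.features)
        np.testing.assert_allclose(pred, ts.scores, atol=1e-6)

    def test_missing_feature_named(self, model):
        m, _ = model
        with pytest.raises(KeyError, match=m.selected_features[0]):
            predict_ns(m, {f: 0.0 for f in m.selected_features[1:]})


class TestSingleFeatureRescore:
    def test_dominant_feature_outperforms_noise_feature(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((150, 2))
        y = np.clip(5 + 2.0 * X[:, 0] + 0.3 * rng.standard_normal(150), 1, 10)
        d = Data(X, y, names=["signal", "noise"])
        j_sig = objective_J(["signal"], d, seed=0)
        j_noise = objective_J(["noise"], d, seed=0)
        assert j_sig < j_noise

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 3))
        y = np.clip(5 + X[:, 1], 1, 10)
        d = Data(X, y)
        cohort = pd.DataFrame(rng.standard_normal((40, 3)), columns=["f0", "f1", "f2"])
        s1 = single_feature_rescore(d, "f1", cohort)
        s2 = single_feature_rescore(d, "f1", cohort)
        np.testing.assert_array_equal(s1, s2)

    def test_combined_model_beats_any_single_feature(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.standard_normal((n, 4))
        theta = np.array([0.9, -0.8, 0.7, 0.6])
        y = np.clip(5.5 + X @ theta + 0.3 * rng.standard_normal(n), 1, 10)
        d = Data(X, y)
        j_all = objective_J(list(d.features.columns), d, seed=1)
        j_singles = [objective_J([f], d, seed=1) for f in d.features.columns]
        assert j_all <= min(j_singles)

    def test_zero_variance_feature_raises(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.zeros(50), rng.standard_normal(50)])
        d = Data(X, rng.uniform(1, 10, 50), names=["flat", "ok"])
        cohort = d.features.copy()
        with pytest.raises(SingularDesignError):
            single_feature_rescore(d, "flat", cohort)
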