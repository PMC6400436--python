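"""Out-of-bag forest, FVE scoring, permutation importance, control model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netnorm import (
    OOBForest,
    control_model,
    covariate_regressions,
    fit_oob_forest,
    fve_score,
    permutation_importance,
)
from netnorm.prediction import COVARIATE_COLUMNS


def make_table(rng, n=60, signal="x0", noise=0.0):
    X = rng.standard_normal((n, 4))
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(4)])
    if signal is None:
        y = rng.standard_normal(n)
    else:
        y = np.sin(2 * df[signal]) + 2 * df[signal] + noise * rng.standard_normal(n)
    df["outcome"] = y
    return df


class TestFveScore:
    def test_constant_predictor_scores_zero(self, rng):
        y = rng.standard_normal(50)
        assert fve_score(y, np.full(50, y.mean())) == pytest.approx(0.0)

    def test_affine_outcome_rescaling_invariance(self, rng):
        y = rng.standard_normal(50)
        pred = y + 0.3 * rng.standard_normal(50)
        f1 = fve_score(y, pred)
        f2 = fve_score(5 * y + 10, 5 * pred + 10)
        assert f1 == pytest.approx(f2)

    def test_zero_variance_outcome_rejected(self):
        with pytest.raises(ValueError):
            fve_score(np.ones(10), np.ones(10))


class TestOOBForest:
    def test_oob_purity(self, rng):
        """No subject's prediction may use a tree that trained on it."""
        df = make_table(rng, n=30)
        forest = OOBForest(n_trees=50, seed=1).fit(
            df[["x0", "x1", "x2", "x3"]].to_numpy(), df["outcome"].to_numpy()
        )
        X = forest._X
        # recompute predictions using only verified out-of-bag trees
        manual = np.zeros(len(X))
        counts = np.zeros(len(X))
        for t, tree in enumerate(forest.trees):
            for i in range(len(X)):
                if forest.inbag[t, i] == 0:
                    manual[i] += tree.predict(X[i : i + 1])[0]
                    counts[i] += 1
        assert (counts > 0).all()
        assert np.allclose(manual / counts, forest.oob_predict())

    def test_noiseless_signal_recovered(self, rng):
        df = make_table(rng, n=200, signal="x0", noise=0.0)
        result = fit_oob_forest(df, ["x0", "x1", "x2", "x3"], n_trees=300, seed=2,
                                compute_importance=False)
        assert result.fve >= 0.8

    def test_null_outcome_scores_near_zero_on_average(self):
        scores = []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            df = make_table(rng, n=40, signal=None)
            r = fit_oob_forest(df, ["x0", "x1", "x2", "x3"], n_trees=120, seed=s,
                               compute_importance=False)
            scores.append(r.fve)
        assert np.mean(scores) <= 0.07  # OOB scoring is unbiased under the null

    def test_deterministic_under_seed(self, rng):
        df = make_table(rng, n=40, noise=0.5)
        r1 = fit_oob_forest(df, ["x0", "x1"], n_trees=100, seed=9, compute_importance=False)
        r2 = fit_oob_forest(df, ["x0", "x1"], n_trees=100, seed=9, compute_importance=False)
        assert np.array_equal(r1.oob_predictions, r2.oob_predictions)


class TestPermutationImportance:
    def test_signal_feature_flagged_above_noise_floor(self, rng):
        df = make_table(rng, n=80, signal="x0", noise=0.3)
        result = fit_oob_forest(df, ["x0", "x1", "x2", "x3"], n_trees=200, seed=3,
                                n_permutations=20)
        assert "x0" in result.significant_features
        assert result.importances["x0"] > result.noise_floor

    def test_constant_feature_has_zero_importance(self, rng):
        df = make_table(rng, n=60, signal="x0", noise=0.2)
        df["x3"] = 1.0  # never split on
        forest = OOBForest(n_trees=150, seed=4).fit(
            df[["x0", "x1", "x2", "x3"]].to_numpy(), df["outcome"].to_numpy()
        )
        imp, floor, sig = permutation_importance(forest, ["x0", "x1", "x2", "x3"], seed=4,
                                                 n_permutations=10)
        assert abs(imp["x3"]) < 1e-12
        assert "x3" not in sig

    def test_single_feature_noise_floor_warns(self, rng):
        df = make_table(rng, n=40, signal="x0", noise=0.2)
        forest = OOBForest(n_trees=100, seed=5).fit(
            df[["x0"]].to_numpy(), df["outcome"].to_numpy()
        )
        with pytest.warns(UserWarning):
            imp, floor, sig = permutation_importance(forest, ["x0"], seed=5, n_permutations=5)
        assert floor == 0.0

    def test_joint_permutation_degrades_at_least_as_much(self, rng):
        """Permuting everything should hurt at least as much as the worst
        single feature, in expectation."""
        df = make_table(rng, n=80, signal="x0", noise=0.3)
        feats = ["x0", "x1", "x2", "x3"]
        forest = OOBForest(n_trees=200, seed=6).fit(
            df[feats].to_numpy(), df["outcome"].to_numpy()
        )
        imp, _, _ = permutation_importance(forest, feats, seed=6, n_permutations=20)
        base = forest.oob_mse()
        rng2 = np.random.default_rng(11)
        deltas = []
        for _ in range(20):
            Xp = forest._X.copy()
            for f in range(4):
                Xp[:, f] = Xp[rng2.permutation(len(Xp)), f]
            deltas.append(forest.oob_mse(Xp) - base)
        assert np.mean(deltas) >= max(imp.values()) - 1e-9


class TestDominantFeatureRecovery:
    def test_planted_metrics_flagged_and_dominant(self):
        """Fig-1-style recovery: when the outcome is planted on clustering
        and path length, both are flagged above the noise floor and their
        importances dominate every other metric's."""
        from netnorm.metrics import METRIC_NAMES
        from netnorm.synthetic import importance_probe_cohort

        want = {"clustering_coefficient", "characteristic_path_length"}
        flagged = dominant = 0
        n_rep = 8
        for rep in range(n_rep):
            table = importance_probe_cohort(n_subjects=26, seed=72000 + rep)
            r = fit_oob_forest(
                table, list(METRIC_NAMES), n_trees=250, seed=rep, n_permutations=15
            )
            flagged += want <= set(r.significant_features)
            planted = [r.importances[m] for m in want]
            others = [r.importances[m] for m in METRIC_NAMES if m not in want]
            dominant += min(planted) > max(others)
        assert flagged >= 0.8 * n_rep
        assert dominant >= 0.8 * n_rep


class TestConfidenceLimits:
    def test_strong_signal_interval_excludes_zero(self, rng):
        df = make_table(rng, n=80, signal="x0", noise=0.1)
        result = fit_oob_forest(df, ["x0", "x1"], n_trees=120, seed=7,
                                n_boot=60, compute_importance=False)
        lo, hi = result.fve_ci
        assert lo > 0
        assert lo <= result.fve <= hi

    def test_no_bootstrap_means_no_interval(self, rng):
        df = make_table(rng, n=40, noise=0.5)
        result = fit_oob_forest(df, ["x0"], n_trees=80, seed=8, n_boot=0,
                                compute_importance=False)
        assert result.fve_ci is None


class TestControlModel:
    def _cohort_table(self, rng, leak=False):
        n = 40
        df = pd.DataFrame({c: rng.standard_normal(n) for c in COVARIATE_COLUMNS})
        df["outcome"] = rng.standard_normal(n)
        if leak:
            df["age"] = df["outcome"]
        return df

    def test_independent_covariates_predict_nothing(self, rng):
        scores = [
            control_model(self._cohort_table(np.random.default_rng(s)), seed=s,
                          n_trees=150, compute_importance=False).fve
            for s in range(10)
        ]
        assert np.mean(scores) < 0.1

    def test_leaked_outcome_is_detected(self, rng):
        r = control_model(self._cohort_table(rng, leak=True), seed=1, n_trees=150,
                          compute_importance=False)
        assert r.fve > 0.5

    def test_missing_covariates_rejected(self, rng):
        df = pd.DataFrame({"age": [1.0, 2.0], "outcome": [0.0, 1.0]})
        with pytest.raises(ValueError):
            control_model(df, seed=0)


class TestCovariateRegressions:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 5, 26)
        df = pd.DataFrame({"age": x, "outcome": 2 * x, "cortical_volume": x,
                           "n_nodes": x})
        out = covariate_regressions(df, pairs=[("age", "outcome")])
        assert out.loc[0, "slope"] == pytest.approx(2.0)
        assert out.loc[0, "p_value"] < 1e-6

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"age": np.ones(10), "outcome": np.arange(10.0)})
        out = covariate_regressions(df, pairs=[("age", "outcome")])
        assert bool(out.loc[0, "constant_x"])
        assert np.isnan(out.loc[0, "slope"])

    def test_null_p_values_uniform(self):
        ps = []
        for s in range(300):
            rng = np.random.default_rng(900 + s)
            df = pd.DataFrame({"age": rng.standard_normal(26),
                               "outcome": rng.standard_normal(26)})
            ps.append(covariate_regressions(df, pairs=[("age", "outcome")]).loc[0, "p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
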