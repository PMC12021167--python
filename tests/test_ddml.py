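"""DDML core: folds, hyperparameter CV, cross-fitting, orthogonal score."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tgua.cohort import generate_cohort
from tgua.config import child_seed
from tgua.ddml import (
    NuisanceFits,
    PLRSpec,
    assign_folds,
    crossfit_nuisance,
    design_matrix,
    estimate_theta,
    naive_plugin_estimate,
    run_ddml,
)
from tgua.learners import LearnerSpec, linear_learner, ridge_learner, select_hyperparameters
from tgua.pipeline import clean_recovery_dgp, confounded_dgp


def _noise_table(n, seed, binary_d=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "y": rng.normal(size=n),
    })
    df["d"] = (rng.random(n) < 0.5).astype(int) if binary_d else rng.normal(size=n)
    return df


class TestAssignFolds:
    def test_even_split(self):
        folds = assign_folds(10, 5, seed=0)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 2]

    def test_cohort_scale_sizes(self):
        sizes = np.bincount(assign_folds(43758, 5, seed=1))
        assert set(sizes) == {8751, 8752}
        assert sizes.sum() == 43758

    def test_deterministic_and_seed_sensitive(self):
        a = assign_folds(100, 4, seed=3)
        b = assign_folds(100, 4, seed=3)
        c = assign_folds(100, 4, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            assign_folds(3, 5, seed=0)


class TestSelectHyperparameters:
    def test_one_point_grid_returned_directly(self):
        params, score = select_hyperparameters(linear_learner(), np.ones((10, 1)),
                                               np.arange(10.0), seed=0)
        assert params == {}
        assert np.isnan(score)

    def test_linear_beats_constant_on_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 2))
        y = 3 * X[:, 0] + rng.normal(scale=0.5, size=300)
        spec = LearnerSpec("linear", ({"kind": "linear"}, {"kind": "mean"}))
        params, score = select_hyperparameters(spec, X, y, seed=1)
        assert params["kind"] == "linear"
        # winner's CV loss is near the noise variance, far below var(y)
        assert score < 0.5 * y.var()

    def test_grid_order_does_not_change_winner(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = 3 * X[:, 0] + rng.normal(scale=0.5, size=300)
        fwd = LearnerSpec("linear", ({"kind": "linear"}, {"kind": "mean"}))
        rev = LearnerSpec("linear", ({"kind": "mean"}, {"kind": "linear"}))
        p1, _ = select_hyperparameters(fwd, X, y, seed=5)
        p2, _ = select_hyperparameters(rev, X, y, seed=5)
        assert p1["kind"] == p2["kind"] == "linear"


class TestCrossfitNuisance:
    def test_pure_noise_outcome_shrinks_to_mean(self):
        df = _noise_table(500, seed=0, binary_d=True)
        spec = PLRSpec(outcome="y", treatment="d", covariates=("x1", "x2"), seed=1)
        fits = crossfit_nuisance(df, spec)
        assert abs(np.mean(fits.lhat) - df["y"].mean()) < 0.1
        assert np.mean(np.abs(fits.lhat - df["y"].mean())) < 3 * df["y"].std() / np.sqrt(500) * 5

    def test_coinflip_treatment_mhat_near_half(self):
        df = _noise_table(1000, seed=3, binary_d=True)
        spec = PLRSpec(outcome="y", treatment="d", covariates=("x1", "x2"), seed=2)
        fits = crossfit_nuisance(df, spec)
        assert abs(np.mean(fits.mhat) - df["d"].mean()) < 0.05
        assert np.all((fits.mhat >= 0.01) & (fits.mhat <= 0.99))

    def test_fold_structure_and_out_of_fold_predictions(self):
        # linear fits computed by hand (direct least squares) per fold
        df = _noise_table(40, seed=5)
        df["y"] = 2.0 * df["x1"] - 1.0 * df["x2"] + df["y"]
        spec = PLRSpec(outcome="y", treatment="d", covariates=("x1", "x2"),
                       n_folds=2, seed=9)
        fits = crossfit_nuisance(df, spec)
        sizes = np.bincount(fits.fold_assignment)
        assert abs(sizes[0] - sizes[1]) <= 1
        X = np.column_stack([np.ones(40), df[["x1", "x2"]].to_numpy()])
        y = df["y"].to_numpy()
        for f in (0, 1):
            test = fits.fold_assignment == f
            beta, *_ = np.linalg.lstsq(X[~test], y[~test], rcond=None)
            assert np.allclose(fits.lhat[test], X[test] @ beta, atol=1e-8)

    def test_degenerate_treatment_raises(self):
        df = _noise_table(50, seed=1, binary_d=True)
        df["d"] = 1
        spec = PLRSpec(outcome="y", treatment="d", covariates=("x1", "x2"), seed=0)
        with pytest.raises(ValueError):
            crossfit_nuisance(df, spec)


class TestEstimateTheta:
    def test_exact_proportional_outcome(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        fits = NuisanceFits(np.zeros(4, dtype=int), np.zeros(4), np.zeros(4),
                            np.nan, np.nan, {})
        res = estimate_theta(2.0 * d, d, fits)
        assert res.theta_hat == pytest.approx(2.0, abs=1e-12)
        assert res.diagnostics["mean_score"] == pytest.approx(0.0, abs=1e-12)

    def test_score_mean_zero_at_solution(self):
        rng = np.random.default_rng(7)
        n = 200
        d = rng.normal(size=n)
        y = 1.5 * d + rng.normal(size=n)
        fits = NuisanceFits(np.zeros(n, dtype=int),
                            rng.normal(scale=0.1, size=n),
                            rng.normal(scale=0.1, size=n), np.nan, np.nan, {})
        res = estimate_theta(y, d, fits)
        assert abs(res.diagnostics["mean_score"]) < 1e-10
        assert res.ci_low <= res.theta_hat <= res.ci_high
        assert res.ci_high - res.theta_hat == pytest.approx(1.959964 * res.se, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        n = 300
        d = rng.normal(size=n)
        y = 0.7 * d + rng.normal(size=n)
        lhat = rng.normal(scale=0.2, size=n)
        mhat = rng.normal(scale=0.2, size=n)
        folds = rng.integers(0, 5, size=n)
        base = estimate_theta(y, d, NuisanceFits(folds, lhat, mhat, 0, 0, {}))
        perm = rng.permutation(n)
        shuf = estimate_theta(y[perm], d[perm],
                              NuisanceFits(folds[perm], lhat[perm], mhat[perm], 0, 0, {}))
        assert shuf.theta_hat == pytest.approx(base.theta_hat, abs=1e-12)
        assert shuf.se == pytest.approx(base.se, abs=1e-12)

    def test_perfectly_predicted_treatment_raises(self):
        d = np.ones(10)
        fits = NuisanceFits(np.zeros(10, dtype=int), np.zeros(10), d.copy(),
                            np.nan, np.nan, {})
        with pytest.raises(ValueError):
            estimate_theta(np.ones(10), d, fits)


class TestOracleEquivalence:
    def test_single_fold_linear_matches_joint_ols(self):
        # Frisch-Waugh-Lovell: partialling-out with whole-sample linear fits
        # equals the D coefficient of OLS of Y on (1, D, X)
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = int(rng.integers(50, 500))
            X = rng.normal(size=(n, 3))
            d = X @ np.array([0.5, -0.2, 0.1]) + rng.normal(size=n)
            y = 2.5 * d + X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
            df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
            df["d"], df["y"] = d, y
            spec = PLRSpec(outcome="y", treatment="d",
                           covariates=("x1", "x2", "x3"), n_folds=1, seed=trial)
            res = run_ddml(df, spec)
            A = np.column_stack([np.ones(n), d, X])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            assert res.theta_hat == pytest.approx(beta[1], abs=1e-8)


class TestRunDDML:
    def test_null_effect_rarely_significant(self):
        dgp = clean_recovery_dgp(theta=0.0, n=2000, g_shape="linear")
        hits = 0
        for s in range(10):
            df = generate_cohort(replace(dgp, seed=child_seed(31, "d", s)))
            res = run_ddml(df, PLRSpec(treatment="TG", seed=child_seed(31, "e", s)))
            hits += abs(res.theta_hat) < 3 * res.se
        assert hits >= 9

    def test_strong_effect_detected(self):
        dgp = clean_recovery_dgp(theta=15.0, n=2000, g_shape="linear")
        for s in range(3):
            df = generate_cohort(replace(dgp, seed=child_seed(37, "d", s)))
            res = run_ddml(df, PLRSpec(treatment="TG", seed=child_seed(37, "e", s)))
            assert res.ci_low > 0
            assert res.p_value < 0.05

    def test_identical_seed_identical_result(self):
        dgp = clean_recovery_dgp(theta=5.0, n=800, g_shape="linear")
        df = generate_cohort(dgp)
        a = run_ddml(df, PLRSpec(treatment="TG", seed=42))
        b = run_ddml(df, PLRSpec(treatment="TG", seed=42))
        assert a.theta_hat == b.theta_hat and a.se == b.se

    def test_per_fold_averaged_variant_close_to_pooled(self):
        dgp = clean_recovery_dgp(theta=10.0, n=2000, g_shape="linear")
        df = generate_cohort(dgp)
        pooled = run_ddml(df, PLRSpec(treatment="TG", seed=1))
        avg = run_ddml(df, PLRSpec(treatment="TG", seed=1,
                                   dml_variant="per-fold-averaged"))
        assert avg.theta_hat == pytest.approx(pooled.theta_hat, abs=3 * pooled.se)


class TestNaivePlugin:
    def test_unconfounded_dgp_agrees_with_ddml(self):
        rng = np.random.default_rng(3)
        n = 3000
        X = rng.normal(size=(n, 3))
        d = rng.normal(size=n)  # independent of X: no confounding
        y = 4.0 * d + X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=n)
        df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        df["d"], df["y"] = d, y
        spec = PLRSpec(outcome="y", treatment="d", covariates=("x1", "x2", "x3"), seed=0)
        ddml = run_ddml(df, spec)
        naive = naive_plugin_estimate(df, spec)
        assert naive.theta_hat == pytest.approx(ddml.theta_hat, abs=4 * ddml.se)

    def test_confounded_dgp_biases_naive_not_ddml(self):
        # regularized outcome learner + confounding: plug-in inherits the
        # shrinkage bias, the orthogonal score does not
        dgp = confounded_dgp(theta=0.0, n=1000)
        ridge = ridge_learner(alphas=(100.0,))
        errs_ddml, errs_naive = [], []
        for s in range(5):
            df = generate_cohort(replace(dgp, seed=child_seed(53, "d", s)))
            spec = PLRSpec(treatment="TG", learner_y=ridge, learner_d=ridge,
                           seed=child_seed(53, "e", s))
            errs_ddml.append(abs(run_ddml(df, spec).theta_hat))
            errs_naive.append(abs(naive_plugin_estimate(df, spec).theta_hat))
        assert np.mean(errs_ddml) < np.mean(errs_naive)
        # the plug-in is systematically displaced from the null
        assert min(errs_naive) > 2.0


def test_design_matrix_encodes_sex_and_rejects_nan():
    df = pd.DataFrame({"sex": ["male", "female"], "age": [50.0, 60.0]})
    X = design_matrix(df, ("sex", "age"))
    assert X[:, 0].tolist() == [1.0, 0.0]
    df.loc[0, "age"] = np.nan
    with pytest.raises(ValueError):
        design_matrix(df, ("sex", "age"))
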