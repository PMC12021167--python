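"""Partially linear double/debiased machine learning (DDML).

Model: Y = theta * D + g(X) + eps, with theta the scalar effect of interest
and g unrestricted.  Stage 1 fits the two nuisance functions
l(X) = E[Y|X] and m(X) = E[D|X] by cross-fitting: the sample is split into
K folds, each fold's predictions come from learners trained on the other
folds.  Stage 2 solves the Neyman-orthogonal partialling-out score on the
residuals u = Y - l(X), v = D - m(X):

    theta_hat = sum(v*u) / sum(v*v)
    psi_i     = v_i * (u_i - theta_hat * v_i)
    var(theta_hat) = mean(psi^2) / (n * mean(v^2)^2)

Orthogonality of psi to first-order nuisance error is what lets flexible,
regularised ML learners stand in for g and m without transmitting their
regularisation bias to theta_hat.  Inference is z-based (normal
approximation); residuals are pooled across folds before solving
("DML2"-style), with a per-fold-averaged variant available.

A plain plug-in estimator (fit E[Y|X], regress the residual on raw D with
no orthogonalisation or sample splitting) is provided as the biased
baseline the debiasing simulations compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_ADJUSTMENT, child_seed
from .learners import (
    LearnerSpec,
    fit_estimator,
    linear_learner,
    make_estimator,
    select_hyperparameters,
)

Z975 = 1.959964  # 97.5% standard-normal quantile used for 95% CIs

#: propensity-type predictions for a binary treatment are clipped here
MHAT_CLIP = (0.01, 0.99)


@dataclass
class PLRSpec:
    """Specification of one partially linear DDML fit."""

    outcome: str = "UA"
    treatment: str = "D"
    covariates: Sequence[str] = DEFAULT_ADJUSTMENT
    n_folds: int = 5
    learner_y: LearnerSpec = field(default_factory=linear_learner)
    learner_d: LearnerSpec = field(default_factory=linear_learner)
    seed: int = 0
    dml_variant: str = "pooled"  # or "per-fold-averaged"
    cv_subsample_cap: int | None = 2000

    def validate(self, n: int) -> None:
        if self.outcome in self.covariates or self.treatment in self.covariates:
            raise ValueError("covariates must be disjoint from outcome/treatment")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.n_folds > n:
            raise ValueError(f"n_folds={self.n_folds} exceeds n={n}")
        if self.dml_variant not in ("pooled", "per-fold-averaged"):
            raise ValueError(f"unknown dml_variant {self.dml_variant!r}")


@dataclass
class NuisanceFits:
    fold_assignment: np.ndarray
    lhat: np.ndarray
    mhat: np.ndarray
    cv_rmse_y: float
    cv_rmse_d: float
    chosen_hyperparameters: dict


@dataclass
class DDMLResult:
    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    spec: PLRSpec | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n": self.n,
            "diagnostics": dict(self.diagnostics),
        }


def design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Numeric covariate matrix; sex is coded 1 = male, 0 = female."""
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append((df["sex"].to_numpy() == "male").astype(float))
        else:
            cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values; preprocess first")
    return X


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition of n rows into k folds whose sizes differ by <= 1."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _is_binary(d: np.ndarray) -> bool:
    return set(np.unique(d)).issubset({0.0, 1.0})


def crossfit_nuisance(df: pd.DataFrame, spec: PLRSpec) -> NuisanceFits:
    """Out-of-fold predictions of E[Y|X] and E[D|X].

    Hyperparameters for each nuisance are chosen once by 5-fold CV, then a
    fresh learner with the chosen point is trained per fold on the
    complementary data.  With ``n_folds=1`` the single learner trains and
    predicts on the full sample (no cross-fitting; used by the exact OLS
    oracle checks).
    """
    n = len(df)
    spec.validate(n)
    X = design_matrix(df, spec.covariates)
    y = df[spec.outcome].to_numpy(dtype=float)
    d = df[spec.treatment].to_numpy(dtype=float)

    folds = assign_folds(n, spec.n_folds, child_seed(spec.seed, "folds"))
    params_y, cv_y = select_hyperparameters(
        spec.learner_y, X, y, k=5, seed=child_seed(spec.seed, "hp_y"),
        subsample_cap=spec.cv_subsample_cap)
    params_d, cv_d = select_hyperparameters(
        spec.learner_d, X, d, k=5, seed=child_seed(spec.seed, "hp_d"),
        subsample_cap=spec.cv_subsample_cap)

    binary = _is_binary(d)
    lhat = np.empty(n)
    mhat = np.empty(n)
    for f in range(spec.n_folds):
        test = folds == f
        train = ~test if spec.n_folds > 1 else np.ones(n, dtype=bool)
        dtr = d[train]
        if binary and (dtr.min() == dtr.max()):
            raise ValueError(f"treatment degenerate (all {dtr[0]:.0f}) in training split for fold {f}")
        est_y = make_estimator(spec.learner_y.kind, params_y,
                               seed=child_seed(spec.seed, "init_y", f))
        fit_estimator(est_y, X[train], y[train])
        lhat[test] = est_y.predict(X[test])
        est_d = make_estimator(spec.learner_d.kind, params_d,
                               seed=child_seed(spec.seed, "init_d", f))
        fit_estimator(est_d, X[train], dtr)
        mhat[test] = est_d.predict(X[test])
    if binary:
        mhat = np.clip(mhat, *MHAT_CLIP)
    if not (np.all(np.isfinite(lhat)) and np.all(np.isfinite(mhat))):
        raise ValueError("non-finite nuisance predictions")
    return NuisanceFits(folds, lhat, mhat, float(np.sqrt(cv_y)) if np.isfinite(cv_y) else cv_y,
                        float(np.sqrt(cv_d)) if np.isfinite(cv_d) else cv_d,
                        {"y": params_y, "d": params_d})


def estimate_theta(y, d, fits: NuisanceFits, variant: str = "pooled") -> DDMLResult:
    """Solve the orthogonal score on residuals and attach sandwich inference."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    n = y.size
    u = y - fits.lhat
    v = d - fits.mhat
    svv = float(v @ v)
    if svv <= 0:
        raise ValueError("zero residual treatment variance; D is perfectly predicted")
    if variant == "per-fold-averaged":
        thetas = []
        for f in np.unique(fits.fold_assignment):
            m = fits.fold_assignment == f
            denom = float(v[m] @ v[m])
            if denom <= 0:
                raise ValueError(f"zero residual treatment variance in fold {f}")
            thetas.append(float(v[m] @ u[m]) / denom)
        theta = float(np.mean(thetas))
    else:
        theta = float(v @ u) / svv
    psi = v * (u - theta * v)
    var = float(np.mean(psi**2)) / (n * float(np.mean(v**2)) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = theta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if theta != 0 else 1.0
    return DDMLResult(
        theta_hat=theta, se=se,
        ci_low=theta - Z975 * se, ci_high=theta + Z975 * se,
        p_value=p, n=n,
        diagnostics={
            "mean_score": float(np.mean(psi)),
            "resid_treatment_var": float(np.mean(v**2)),
            "variant": variant,
        },
    )


def run_ddml(df: pd.DataFrame, spec: PLRSpec) -> DDMLResult:
    """Full DDML fit: folds -> hyperparameters -> cross-fit -> orthogonal score."""
    fits = crossfit_nuisance(df, spec)
    res = estimate_theta(df[spec.outcome].to_numpy(dtype=float),
                         df[spec.treatment].to_numpy(dtype=float),
                         fits, variant=spec.dml_variant)
    res.spec = spec
    res.diagnostics.update({
        "cv_rmse_y": fits.cv_rmse_y,
        "cv_rmse_d": fits.cv_rmse_d,
        "chosen_hyperparameters": fits.chosen_hyperparameters,
        "fold_sizes": np.bincount(fits.fold_assignment).tolist(),
        "seed": spec.seed,
    })
    return res


def naive_plugin_estimate(df: pd.DataFrame, spec: PLRSpec) -> DDMLResult:
    """Single-stage plug-in baseline (intentionally not debiased).

    Fits E[Y|X] on the full sample with the (possibly regularised)
    outcome learner, then regresses the outcome residual on raw D with an
    intercept.  No orthogonalisation of D, no cross-fitting: the outcome
    learner's regularisation bias flows straight into the slope.
    """
    n = len(df)
    spec.validate(n)
    X = design_matrix(df, spec.covariates)
    y = df[spec.outcome].to_numpy(dtype=float)
    d = df[spec.treatment].to_numpy(dtype=float)
    params_y, _ = select_hyperparameters(
        spec.learner_y, X, y, k=5, seed=child_seed(spec.seed, "hp_y"),
        subsample_cap=spec.cv_subsample_cap)
    est = make_estimator(spec.learner_y.kind, params_y,
                         seed=child_seed(spec.seed, "init_y", 0))
    fit_estimator(est, X, y)
    u = y - est.predict(X)
    A = np.column_stack([np.ones(n), d])
    coef, *_ = np.linalg.lstsq(A, u, rcond=None)
    theta = float(coef[1])
    resid = u - A @ coef
    dc = d - d.mean()
    sdd = float(dc @ dc)
    se = float(np.sqrt((resid @ resid) / max(n - 2, 1) / sdd)) if sdd > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(theta / se))) if se > 0 else 1.0
    return DDMLResult(theta_hat=theta, se=se, ci_low=theta - Z975 * se,
                      ci_high=theta + Z975 * se, p_value=p, n=n,
                      diagnostics={"estimator": "naive_plugin"})
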