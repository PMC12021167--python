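"""Subgroup heterogeneity grid and cohort descriptives.

The grid runs the DDML estimator over percentile treatments crossed with
subgroups (overall, by sex, sex x age band, and sex x HGB stratum within
the 50-65 band).  TG thresholds are recomputed inside each subgroup, so a
"median TG" treatment means the subgroup's own median.  Any covariate that
defines a stratum is dropped from that stratum's adjustment set (sex in
sex-stratified runs, HGB in anemia-stratified runs); age stays in as a
continuous control within age bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_BANDS, ANEMIA_CUTOFF_G_L, child_seed
from .ddml import PLRSpec, run_ddml
from .treatment import compute_thresholds, dichotomize

logger = logging.getLogger(__name__)

#: a subgroup must have at least this many rows per fold to be estimated
MIN_ROWS_PER_FOLD = 10

_TREATMENT_COL = "_tg_indicator"


@dataclass(frozen=True)
class SubgroupSpec:
    """One cell of the stratification grid; 'all' leaves a margin unrestricted.

    Age bands are left-open/right-closed at 50 and 65 (age exactly 50 falls
    in '<=50', exactly 65 in '50-65'); HGB exactly 115 g/L is anemic.
    """

    sex: str = "all"          # male | female | all
    age_band: str = "all"     # <=50 | 50-65 | >65 | all
    hgb_band: str = "all"     # <=115 | >115 | all

    def label(self) -> str:
        return f"sex={self.sex}|age={self.age_band}|hgb={self.hgb_band}"


def filter_subgroup(table: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    mask = np.ones(len(table), dtype=bool)
    if spec.sex != "all":
        mask &= (table["sex"] == spec.sex).to_numpy()
    if spec.age_band != "all":
        age = table["age"].to_numpy(dtype=float)
        if spec.age_band == "<=50":
            mask &= age <= 50.0
        elif spec.age_band == "50-65":
            mask &= (age > 50.0) & (age <= 65.0)
        elif spec.age_band == ">65":
            mask &= age > 65.0
        else:
            raise ValueError(f"unknown age band {spec.age_band!r}")
    if spec.hgb_band != "all":
        hgb = table["HGB"].to_numpy(dtype=float)
        if spec.hgb_band == "<=115":
            mask &= hgb <= ANEMIA_CUTOFF_G_L
        elif spec.hgb_band == ">115":
            mask &= hgb > ANEMIA_CUTOFF_G_L
        else:
            raise ValueError(f"unknown HGB band {spec.hgb_band!r}")
    out = table.loc[mask]
    if len(out) == 0:
        raise ValueError(f"subgroup {spec.label()} is empty")
    return out


def adjusted_covariates(base_covariates, spec: SubgroupSpec) -> list[str]:
    """Drop stratum-defining covariates from the adjustment set."""
    covs = list(base_covariates)
    if spec.sex != "all" and "sex" in covs:
        covs.remove("sex")
    if spec.hgb_band != "all" and "HGB" in covs:
        covs.remove("HGB")
    return covs


def run_grid(table: pd.DataFrame, subgroups: list[SubgroupSpec],
             percentiles, base_spec: PLRSpec) -> pd.DataFrame:
    """DDML over every (subgroup, percentile) cell.

    Per-cell seeds derive from the base seed and the cell's labels, so
    results do not depend on the order subgroups are listed in.  Subgroups
    too small for the fold count, or with a degenerate indicator, are
    skipped with a logged warning.
    """
    rows = []
    for sg in subgroups:
        sub = filter_subgroup(table, sg).reset_index(drop=True)
        if len(sub) < MIN_ROWS_PER_FOLD * base_spec.n_folds:
            logger.warning("skipping %s: n=%d below %d per fold x %d folds",
                           sg.label(), len(sub), MIN_ROWS_PER_FOLD, base_spec.n_folds)
            continue
        covs = adjusted_covariates(base_spec.covariates, sg)
        specs = compute_thresholds(sub["TG"].to_numpy(dtype=float), percentiles)
        for tspec in specs:
            dvec = dichotomize(sub["TG"].to_numpy(dtype=float), tspec)
            if dvec.min() == dvec.max():
                logger.warning("skipping %s p=%.2f: degenerate indicator", sg.label(), tspec.percentile)
                continue
            cell = sub.copy()
            cell[_TREATMENT_COL] = dvec
            seed = child_seed(base_spec.seed, sg.label(), f"p={tspec.percentile:.4f}")
            spec = replace(base_spec, treatment=_TREATMENT_COL, covariates=covs, seed=seed)
            res = run_ddml(cell, spec)
            rows.append({
                "sex": sg.sex, "age_band": sg.age_band, "hgb_band": sg.hgb_band,
                "percentile": tspec.percentile, "tg_threshold": tspec.threshold,
                "theta_hat": res.theta_hat, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "n": res.n,
            })
    return pd.DataFrame(rows)


DESCRIBE_VARIABLES = ("UA", "TG", "GLU", "CREA", "CHE", "CKMB", "HGB", "sodium")


def describe_cohort(table: pd.DataFrame, variables=DESCRIBE_VARIABLES) -> dict:
    """Sex-stratified descriptives: n, share, mean, pooled t per variable,
    plus the chi-square statistic of the age-band x sex contingency table."""
    male = table.loc[table["sex"] == "male"]
    female = table.loc[table["sex"] == "female"]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("a sex stratum is empty")
    rows = []
    for var in variables:
        a = male[var].dropna().to_numpy(dtype=float)
        b = female[var].dropna().to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(t) and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0  # zero pooled variance with equal means
        rows.append({
            "variable": var,
            "male_n": len(a), "male_ratio": len(a) / (len(a) + len(b)),
            "male_mean": float(a.mean()),
            "female_n": len(b), "female_ratio": len(b) / (len(a) + len(b)),
            "female_mean": float(b.mean()),
            "t": float(t), "p": float(p),
        })
    bands = pd.Categorical(
        np.where(table["age"] <= 50, "<=50", np.where(table["age"] <= 65, "50-65", ">65")),
        categories=list(AGE_BANDS))
    contingency = pd.crosstab(bands, table["sex"])
    chi2, chi2_p, _, _ = stats.chi2_contingency(contingency, correction=False)
    return {
        "variables": pd.DataFrame(rows),
        "age_band_by_sex": contingency,
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
    }
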