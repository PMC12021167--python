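"""Data preparation: core-field exclusion, first-record deduplication,
training-mean imputation and 1% winsorization.

The stages run in a fixed order matching a routine retrospective-cohort
cleaning protocol: records missing the outcome, exposure, or demographics
are excluded outright; repeat admissions are collapsed to the initial
record; remaining missing lab values are filled with the analysis-sample
mean; finally each continuous variable is clipped at its 1st and 99th
percentiles.  Imputation means are computed once on the post-exclusion
sample (not per cross-fitting fold); the mild leakage this implies is a
documented property of the protocol, not of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CORE_FIELDS, LAB_COVARIATES, WINSOR_VARIABLES


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_dropped_missing_core: int = 0
    n_dropped_duplicates: int = 0
    n_imputed_cells_per_covariate: dict = field(default_factory=dict)
    winsor_bounds_per_variable: dict = field(default_factory=dict)
    n_output: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_missing_core": self.n_dropped_missing_core,
            "n_dropped_duplicates": self.n_dropped_duplicates,
            "n_imputed_cells_per_covariate": dict(self.n_imputed_cells_per_covariate),
            "winsor_bounds_per_variable": {k: list(v) for k, v in self.winsor_bounds_per_variable.items()},
            "n_output": self.n_output,
        }


def drop_incomplete_core(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows missing outcome (UA), exposure (TG), sex or age."""
    for col in CORE_FIELDS:
        if col not in table.columns:
            raise KeyError(f"required column {col!r} absent")
    keep = table[list(CORE_FIELDS)].notna().all(axis=1)
    return table.loc[keep].copy(), int((~keep).sum())


def dedup_first_record(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep only the record with minimal record_index per patient."""
    if "patient_id" not in table.columns or "record_index" not in table.columns:
        raise KeyError("patient_id and record_index columns required")
    idx = table.groupby("patient_id")["record_index"].idxmin()
    kept = table.loc[sorted(idx)].copy()
    return kept, len(table) - len(kept)


def impute_training_mean(table: pd.DataFrame,
                         covariates: tuple[str, ...] = LAB_COVARIATES
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill missing covariate cells with the covariate's observed mean.

    The outcome and exposure are never imputed; a covariate with no
    observed values at all is an error.
    """
    out = table.copy()
    counts: dict[str, int] = {}
    for col in covariates:
        vals = out[col]
        n_missing = int(vals.isna().sum())
        if n_missing == len(vals):
            raise ValueError(f"covariate {col!r} is entirely missing")
        if n_missing:
            out[col] = vals.fillna(vals.mean())
        counts[col] = n_missing
    return out, counts


def winsorize(values, lower_q: float = 0.01, upper_q: float = 0.99) -> np.ndarray:
    """Clip a vector at its lower_q and upper_q quantiles.

    Quantiles use linear interpolation between order statistics — the one
    quantile definition used package-wide (also for treatment thresholds).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not (0.0 < lower_q < upper_q < 1.0):
        raise ValueError(f"quantiles must satisfy 0 < lower < upper < 1, got ({lower_q}, {upper_q})")
    lo, hi = np.quantile(x, [lower_q, upper_q], method="linear")
    return np.clip(x, lo, hi)


def run_preprocess(table: pd.DataFrame,
                   covariates: tuple[str, ...] = LAB_COVARIATES,
                   winsor_vars: tuple[str, ...] = WINSOR_VARIABLES,
                   lower_q: float = 0.01, upper_q: float = 0.99
                   ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run all four stages in order and return the cleaned table + report."""
    report = PreprocessReport(n_input=len(table))
    table, report.n_dropped_missing_core = drop_incomplete_core(table)
    table, report.n_dropped_duplicates = dedup_first_record(table)
    table, report.n_imputed_cells_per_covariate = impute_training_mean(table, covariates)
    for var in winsor_vars:
        x = table[var].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [lower_q, upper_q], method="linear")
        table[var] = np.clip(x, lo, hi)
        report.winsor_bounds_per_variable[var] = (float(lo), float(hi))
    report.n_output = len(table)
    return table.reset_index(drop=True), report
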