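"""Synthetic inpatient cohort generator.

Emulates a hospital laboratory extract: one row per admission record with
demographics (age, sex), the outcome uric acid (UA, umol/L), the exposure
triglycerides (TG, mmol/L), and routine labs (GLU, CREA, CHE, CKMB, HGB,
sodium).  The causal structure is partially linear with a known
subgroup-specific TG effect, so every downstream estimator can be tested
against ground truth.  Messiness — duplicate admissions, missing covariate
cells, multiplicative outliers — is injected after generation, mirroring
what the preprocessing stage has to clean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    ANEMIA_CUTOFF_G_L,
    LAB_COVARIATES,
    DGPConfig,
)

TG_FLOOR = 0.1  # mmol/L
UA_FLOOR = 50.0  # umol/L

COLUMNS = [
    "patient_id",
    "record_index",
    "age",
    "sex",
    "UA",
    "TG",
    "GLU",
    "CREA",
    "CHE",
    "CKMB",
    "HGB",
    "sodium",
]

_AGE_RANGES = {"<=50": (18.0, 50.0), "50-65": (50.0, 65.0), ">65": (65.0, 95.0)}


def _sex_value(means: tuple[float, float], male: np.ndarray) -> np.ndarray:
    return np.where(male, means[0], means[1])


def _draw_labs(cfg: DGPConfig, rng: np.random.Generator, male: np.ndarray,
               anemic: np.ndarray) -> dict[str, np.ndarray]:
    """Draw the lab covariates (everything except age/sex/TG/UA)."""
    n = male.size
    m = cfg.covariate_means_by_sex
    s = cfg.covariate_sds
    labs = {}
    for var in ("GLU", "CREA", "CHE", "sodium"):
        labs[var] = rng.normal(_sex_value(m[var], male), s[var])
    hgb_mean = np.where(anemic, _sex_value(m["HGB_anemic"], male),
                        _sex_value(m["HGB_nonanemic"], male))
    hgb_sd = np.where(anemic, s["HGB_anemic"], s["HGB_nonanemic"])
    labs["HGB"] = rng.normal(hgb_mean, hgb_sd)
    labs["CKMB"] = np.exp(rng.normal(np.log(_sex_value(m["CKMB_median"], male)),
                                     s["CKMB_log_sigma"], size=n))
    # lab panels report strictly positive values
    for var in ("GLU", "CREA", "CHE", "sodium", "HGB"):
        labs[var] = np.maximum(labs[var], 0.5)
    return labs


def exposure_mean(cfg: DGPConfig, sex: np.ndarray, glu: np.ndarray) -> np.ndarray:
    """Conditional mean m(X) of TG: sex-specific center plus a glucose term."""
    male = np.asarray(sex) == "male"
    tg_center = _sex_value(cfg.covariate_means_by_sex["TG"], male)
    glu_center = _sex_value(cfg.covariate_means_by_sex["GLU"], male)
    return tg_center + cfg.tg_glu_slope * (np.asarray(glu, dtype=float) - glu_center)


def age_band_of(age: np.ndarray) -> np.ndarray:
    """Band labels with left-open/right-closed cuts at 50 and 65."""
    age = np.asarray(age, dtype=float)
    return np.where(age <= 50.0, "<=50", np.where(age <= 65.0, "50-65", ">65"))


def hgb_band_of(hgb: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(hgb, dtype=float) <= ANEMIA_CUTOFF_G_L, "<=115", ">115")


def theta_per_row(cfg: DGPConfig, df: pd.DataFrame) -> np.ndarray:
    """True TG effect for each row, read off its (sex, age band, HGB band)."""
    bands = age_band_of(df["age"].to_numpy())
    hgb = hgb_band_of(df["HGB"].to_numpy())
    sex = df["sex"].to_numpy()
    return np.array([cfg.theta_by_subgroup[(s, a, h)]
                     for s, a, h in zip(sex, bands, hgb)])


def confounder_values(cfg: DGPConfig, df: pd.DataFrame) -> np.ndarray:
    """Evaluate the confounding function g(X) on realized covariates.

    Includes the centering term -theta(subgroup)*m(X) so that the marginal
    UA mean sits near the configured sex-specific base regardless of theta.
    Exposed so tests can regress UA on TG with g known.
    """
    male = (df["sex"].to_numpy() == "male")
    m = cfg.covariate_means_by_sex
    c = cfg.g_coef
    base = _sex_value(m["UA_base"], male)
    theta = theta_per_row(cfg, df)
    m_tg = exposure_mean(cfg, df["sex"].to_numpy(), df["GLU"].to_numpy())
    g = (
        base
        - theta * m_tg
        + c["glu"] * (df["GLU"].to_numpy() - 8.0)
        + c["hgb"] * (df["HGB"].to_numpy() - 140.0)
        + c["che"] * (df["CHE"].to_numpy() - 7650.0)
    )
    age = df["age"].to_numpy(dtype=float)
    crea = df["CREA"].to_numpy(dtype=float)
    ckmb = df["CKMB"].to_numpy(dtype=float)
    if cfg.g_shape == "additive-nonlinear":
        g = g + c["age_quad"] * (((age - 60.0) / 15.0) ** 2 - 1.0)
        g = g + c["crea_tanh"] * np.tanh((crea - 83.0) / 30.0)
        g = g + c["ckmb_log"] * np.log(np.maximum(ckmb, 1e-6) / 2.0)
    else:
        g = g + c["age_lin"] * (age - 60.0)
        g = g + c["crea_lin"] * (crea - 83.0)
        g = g + c["ckmb_lin"] * (ckmb - 2.0)
    return g


def _generate_records(cfg: DGPConfig, rng: np.random.Generator, sex: np.ndarray,
                      age: np.ndarray, anemic: np.ndarray) -> pd.DataFrame:
    """Draw labs, TG and UA for fixed demographics (used for both the
    initial record and the re-noised duplicate of a patient)."""
    male = sex == "male"
    labs = _draw_labs(cfg, rng, male, anemic)
    m_tg = exposure_mean(cfg, sex, labs["GLU"])
    tg = np.maximum(m_tg + rng.normal(0.0, cfg.noise_sd_tg, size=sex.size), TG_FLOOR)
    df = pd.DataFrame({"age": age, "sex": sex, "TG": tg, **labs})
    theta = theta_per_row(cfg, df)
    g = confounder_values(cfg, df)
    ua = theta * tg + g + rng.normal(0.0, cfg.noise_sd_y, size=sex.size)
    df["UA"] = np.maximum(ua, UA_FLOOR)
    return df


def generate_cohort(cfg: DGPConfig) -> pd.DataFrame:
    """Generate the synthetic cohort table.

    Returns at least ``cfg.n_patients`` rows (duplicate admissions add
    rows with ``record_index=2``).  Deterministic: identical configs give
    byte-identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_patients

    sex = np.where(rng.random(n) < cfg.sex_ratio_male, "male", "female")
    band = rng.choice(np.array(["<=50", "50-65", ">65"]), size=n,
                      p=np.asarray(cfg.age_band_weights, dtype=float) /
                      np.sum(cfg.age_band_weights))
    lo = np.array([_AGE_RANGES[b][0] for b in band])
    hi = np.array([_AGE_RANGES[b][1] for b in band])
    age = np.round(lo + (hi - lo) * rng.random(n), 1)
    anemic = rng.random(n) < cfg.anemia_rate

    df = _generate_records(cfg, rng, sex, age, anemic)
    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    df.insert(1, "record_index", 1)

    # duplicate admissions: a second, re-noised record for a random subset
    n_dup = int(round(cfg.dup_rate * n))
    if n_dup > 0:
        idx = rng.choice(n, size=n_dup, replace=False)
        idx.sort()
        dup = _generate_records(cfg, rng, sex[idx], age[idx], anemic[idx])
        dup.insert(0, "patient_id", [f"P{i:06d}" for i in idx])
        dup.insert(1, "record_index", 2)
        df = pd.concat([df, dup], ignore_index=True)

    # multiplicative outliers on UA / TG / CREA
    n_rows = len(df)
    n_out = int(round(cfg.outlier_rate * n_rows))
    if n_out > 0:
        rows = rng.choice(n_rows, size=n_out, replace=False)
        cols = rng.choice(np.array(["UA", "TG", "CREA"]), size=n_out)
        factors = rng.uniform(3.0, 6.0, size=n_out)
        for r, cname, f in zip(rows, cols, factors):
            df.loc[r, cname] = df.loc[r, cname] * f

    # MCAR missingness over lab covariates only (never UA/TG/sex/age)
    if cfg.missing_rate > 0:
        for var in LAB_COVARIATES:
            mask = rng.random(n_rows) < cfg.missing_rate
            df.loc[mask, var] = np.nan

    return df[COLUMNS]


def true_effect(cfg: DGPConfig, sex: str, age_band: str, hgb_band: str) -> float:
    """True generator effect (umol/L UA per mmol/L TG) for one subgroup cell."""
    key = (sex, age_band, hgb_band)
    if key not in cfg.theta_by_subgroup:
        raise KeyError(f"unknown subgroup cell {key}")
    return float(cfg.theta_by_subgroup[key])
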