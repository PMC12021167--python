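"""Configuration objects and shared vocabulary for the TG->UA analysis.

The synthetic cohort is parameterised by :class:`DGPConfig`, which fixes the
data-generating process completely: given an identical config (including its
seed) the generated table is byte-identical.  Sex-specific covariate centers
default to the published descriptives of a large Beijing inpatient cohort
(43,758 admissions, 57.7% male); dispersions and rates the source tables do
not report carry documented defaults chosen to look like routine inpatient
laboratory panels.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

SEXES = ("male", "female")
AGE_BANDS = ("<=50", "50-65", ">65")
HGB_BANDS = ("<=115", ">115")

#: laboratory covariates that may carry missing values in raw extracts
LAB_COVARIATES = ("GLU", "CREA", "CHE", "CKMB", "HGB", "sodium")

#: fields a record must have to enter the analysis at all
CORE_FIELDS = ("UA", "TG", "sex", "age")

#: default adjustment set for the overall model (sodium deliberately excluded)
DEFAULT_ADJUSTMENT = ("sex", "age", "GLU", "CREA", "CHE", "CKMB", "HGB")

#: continuous variables clipped by the 1% winsorization step
WINSOR_VARIABLES = ("UA", "TG", "GLU", "CREA", "CHE", "CKMB", "HGB", "sodium")

DEFAULT_PERCENTILES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

ANEMIA_CUTOFF_G_L = 115.0  # HGB at or below this value = anemic stratum


def subgroup_cells() -> list[tuple[str, str, str]]:
    """All (sex, age band, HGB band) cells the heterogeneity grid can form."""
    return [(s, a, h) for s in SEXES for a in AGE_BANDS for h in HGB_BANDS]


def _default_theta() -> dict[tuple[str, str, str], float]:
    # Known subgroup effects, in umol/L UA per mmol/L TG.  The 50-65 band
    # carries the anemia contrast (null effect in the anemic stratum).
    theta: dict[tuple[str, str, str], float] = {}
    for sex in SEXES:
        for hgb in HGB_BANDS:
            theta[(sex, "<=50", hgb)] = 10.0
            theta[(sex, ">65", hgb)] = 6.0
        theta[(sex, "50-65", "<=115")] = 0.0
        theta[(sex, "50-65", ">115")] = 15.0
    return theta


def _default_means() -> dict[str, tuple[float, float]]:
    # (male, female) centers; HGB is a two-component mixture, CKMB lognormal.
    return {
        "TG": (1.76, 1.53),
        "UA_base": (385.23, 316.98),
        "GLU": (8.13, 7.92),
        "CREA": (93.91, 72.92),
        "CHE": (7701.89, 7603.14),
        "sodium": (141.06, 141.03),
        "CKMB_median": (2.0, 2.0),
        "HGB_nonanemic": (148.67, 136.13),
        "HGB_anemic": (99.23, 102.65),
    }


def _default_sds() -> dict[str, float]:
    return {
        "GLU": 3.0,
        "CREA": 24.0,
        "CHE": 1750.0,
        "sodium": 3.0,
        "HGB_nonanemic": 11.0,
        "HGB_anemic": 7.0,
        "CKMB_log_sigma": 0.9,
    }


def _default_g_coef() -> dict[str, float]:
    # Additive confounding function g(X); the nonlinear terms act on
    # covariates (age, CREA, CKMB) that do not enter the TG model m(X).
    return {
        "glu": 2.5,
        "hgb": 0.25,
        "che": 0.004,
        "age_quad": 20.0,
        "crea_tanh": 40.0,
        "ckmb_log": 4.0,
        "age_lin": 0.5,
        "crea_lin": 0.6,
        "ckmb_lin": 1.0,
    }


@dataclass
class DGPConfig:
    """Full specification of the synthetic-cohort data-generating process.

    UA is generated as ``UA = theta(subgroup) * TG + g(X) + eps`` with
    ``eps ~ N(0, noise_sd_y)``; TG as ``m(X) + nu`` with
    ``nu ~ N(0, noise_sd_tg)`` floored at 0.1 mmol/L.  ``m(X)`` depends on
    sex and glucose only; ``g(X)`` is either linear or additive-nonlinear
    in the remaining covariates.
    """

    n_patients: int = 20_000
    seed: int = 0
    dup_rate: float = 0.05
    missing_rate: float = 0.03
    outlier_rate: float = 0.01
    sex_ratio_male: float = 0.577
    # admission shares of the <=50 / 50-65 / >65 bands (16,383 / 13,897 /
    # 13,478 of 43,758 in the reference descriptives)
    age_band_weights: tuple[float, float, float] = (0.3744, 0.3176, 0.3080)
    anemia_rate: float = 0.085
    covariate_means_by_sex: dict[str, tuple[float, float]] = field(default_factory=_default_means)
    covariate_sds: dict[str, float] = field(default_factory=_default_sds)
    theta_by_subgroup: dict[tuple[str, str, str], float] = field(default_factory=_default_theta)
    g_shape: str = "additive-nonlinear"
    g_coef: dict[str, float] = field(default_factory=_default_g_coef)
    tg_glu_slope: float = 0.05
    noise_sd_y: float = 45.0
    noise_sd_tg: float = 0.5

    def validate(self) -> None:
        for name in ("dup_rate", "missing_rate", "outlier_rate", "sex_ratio_male", "anemia_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v!r}")
        w = np.asarray(self.age_band_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"age_band_weights must be 3 non-negative fractions summing to 1, got {self.age_band_weights!r}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.g_shape not in ("linear", "additive-nonlinear"):
            raise ValueError(f"unknown g_shape {self.g_shape!r}")
        for name in ("noise_sd_y", "noise_sd_tg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive real, got {v!r}")
        missing = [c for c in subgroup_cells() if c not in self.theta_by_subgroup]
        if missing:
            raise ValueError(f"theta_by_subgroup lacks cells: {missing}")
        for key, val in self.theta_by_subgroup.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite theta for cell {key}")
        for key, val in self.covariate_sds.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"covariate sd {key} must be positive")

    def with_uniform_theta(self, theta: float) -> "DGPConfig":
        """Copy of the config with the same effect in every subgroup cell."""
        return replace(self, theta_by_subgroup={c: float(theta) for c in subgroup_cells()})

    def uniform_theta_value(self) -> float:
        """The single true effect, if all cells share one; error otherwise."""
        vals = set(self.theta_by_subgroup.values())
        if len(vals) != 1:
            raise ValueError("theta_by_subgroup is not uniform across cells")
        return vals.pop()

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_band_weights"] = list(self.age_band_weights)
        d["theta_by_subgroup"] = {"/".join(k): v for k, v in self.theta_by_subgroup.items()}
        d["covariate_means_by_sex"] = {k: list(v) for k, v in self.covariate_means_by_sex.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DGPConfig":
        d = dict(d)
        if "age_band_weights" in d:
            d["age_band_weights"] = tuple(d["age_band_weights"])
        if "theta_by_subgroup" in d:
            d["theta_by_subgroup"] = {tuple(k.split("/")): float(v) for k, v in d["theta_by_subgroup"].items()}
        if "covariate_means_by_sex" in d:
            d["covariate_means_by_sex"] = {k: tuple(v) for k, v in d["covariate_means_by_sex"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DGPConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable sha256 of the canonical JSON form (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def child_seed(base: int, *labels) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a base seed and labels.

    Labels may be strings or ints; strings are hashed with crc32 so the
    derivation depends on the label values, not on iteration order.
    """
    keys = [int(base) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            keys.append(int(lab) & 0x7FFFFFFF)
        else:
            keys.append(zlib.crc32(str(lab).encode()) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
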