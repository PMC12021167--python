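"""Percentile dichotomization of the triglyceride exposure.

TG is sorted and cut at a fixed ladder of percentiles (10%...90% by
default); each cut yields a binary treatment: 1 for values strictly above
the threshold ("surpassing"), 0 at or below.  Ties go to 0 — strict
exceedance — which is the documented, configurable convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_PERCENTILES


@dataclass(frozen=True)
class TreatmentSpec:
    percentile: float
    threshold: float  # mmol/L
    name: str


def compute_thresholds(tg, percentiles=DEFAULT_PERCENTILES) -> list[TreatmentSpec]:
    """One TreatmentSpec per percentile, using linear-interpolation quantiles."""
    x = np.asarray(tg, dtype=float)
    if x.size == 0:
        raise ValueError("empty TG vector")
    ps = [float(p) for p in percentiles]
    if any(not 0.0 < p < 1.0 for p in ps):
        raise ValueError("percentiles must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(ps, ps[1:])):
        raise ValueError("percentiles must be strictly increasing")
    thresholds = np.quantile(x, ps, method="linear")
    return [TreatmentSpec(p, float(t), f"tg_gt_p{int(round(100 * p))}")
            for p, t in zip(ps, thresholds)]


def dichotomize(tg, spec: TreatmentSpec) -> np.ndarray:
    """Binary treatment: 1 where TG strictly exceeds the threshold."""
    if not np.isfinite(spec.threshold):
        raise ValueError("threshold must be finite")
    return (np.asarray(tg, dtype=float) > spec.threshold).astype(np.int64)


def threshold_table(tg, percentiles=DEFAULT_PERCENTILES) -> pd.DataFrame:
    """Summary table: percentile, threshold, treated/control counts."""
    specs = compute_thresholds(tg, percentiles)
    rows = []
    for s in specs:
        d = dichotomize(tg, s)
        rows.append({"percentile": s.percentile, "threshold": s.threshold,
                     "n_treated": int(d.sum()), "n_control": int(d.size - d.sum())})
    return pd.DataFrame(rows)
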