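#!/usr/bin/env python
"""Heterogeneity grids: by sex, by sex x age band, and the anemia contrast.

Reruns the percentile-threshold DDML inside each stratum (thresholds
recomputed within stratum; stratum-defining covariates dropped from the
adjustment set).  The headline contrast lives in the 50-65 age band:
the generator gives anemic patients (HGB <= 115 g/L) a null TG effect and
non-anemic patients a strong one, and the grid should show exactly that —
anemic CIs hugging zero, non-anemic CIs well above it.
"""

from pathlib import Path

import pandas as pd

from tgua.config import DEFAULT_PERCENTILES
from tgua.ddml import PLRSpec
from tgua.heterogeneity import run_grid
from tgua.pipeline import standard_subgroups

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

LAYOUTS = ("by_sex", "by_sex_age", "by_sex_hgb_50_65")


def main() -> None:
    clean = pd.read_csv(ROOT / "scratch" / "cohort_clean.csv")
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    spec = PLRSpec(n_folds=5, seed=SEED)  # linear nuisances across 48 cells
    for layout in LAYOUTS:
        grid = run_grid(clean, standard_subgroups(layout), DEFAULT_PERCENTILES, spec)
        grid.to_csv(outdir / f"grid_{layout}.csv", index=False)
        print(f"== {layout}: {len(grid)} cells ==")
        if layout == "by_sex_hgb_50_65":
            for (sex, hgb), g in grid.groupby(["sex", "hgb_band"]):
                n_sig = int((g.p_value < 0.05).sum())
                print(f"  {sex:6s} HGB {hgb:5s}: n={int(g.n.iloc[0]):5d}  "
                      f"median theta {g.theta_hat.median():7.2f}  "
                      f"{n_sig}/9 thresholds p<0.05")
    print("\nanemic strata should show ~0 significant thresholds; "
          "non-anemic strata should be significant nearly everywhere.")


if __name__ == "__main__":
    main()
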