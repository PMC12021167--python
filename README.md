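# tgua — triglycerides, uric acid, and who the association holds for

`tgua` is an analysis package for estimating the effect of serum
triglycerides (TG, mmol/L) on serum uric acid (UA, μmol/L) in inpatient
laboratory data, and for asking *in which patients* that effect exists.
It is aimed at biostatisticians and epidemiologists working with
hospital-record extracts, where the association of interest is tangled
with demographics and routine labs (glucose, creatinine, cholinesterase,
CKMB, hemoglobin) and where subgroup structure — sex, age band, anemia —
may switch the association on or off.

The estimator at the core is a from-scratch partially linear
double/debiased machine-learning (DDML) model

    UA = θ·D + g(X) + ε,        D = m(X) + ν,

where D is TG dichotomized at a percentile threshold (1 = strictly above)
or raw TG, and g, m are fit by pluggable ML learners (OLS, ridge, or a
cross-validated single-hidden-layer neural network). Nuisances are
cross-fitted over K folds, and θ is solved from the Neyman-orthogonal
partialling-out score on the residuals u = UA − ℓ̂(X), v = D − m̂(X):

    θ̂ = Σ vᵢuᵢ / Σ vᵢ²,    Var(θ̂) = mean(ψ²)/(n·mean(v²)²),
    ψᵢ = vᵢ(uᵢ − θ̂vᵢ),

with z-based 95% CIs and p-values. Orthogonality plus cross-fitting is
what keeps the learners' regularization bias out of θ̂ — the package
ships a deliberately naive plug-in estimator so the difference is
measurable, not rhetorical.

Because hospital records cannot ship with the package, it includes a
first-class synthetic cohort generator with a *known* partially linear
truth: sex-specific lab marginals, an anemic hemoglobin mixture,
duplicate admissions, missing cells and outliers, and a subgroup effect
map θ(sex, age band, HGB band) that downstream estimates can be tested
against. The default map encodes the headline contrast: among patients
aged 50–65, θ = 0 if anemic (HGB ≤ 115 g/L) and θ = 15 μmol/L per mmol/L
if not. See `docs/methods.md` for the full model and its limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a 20,000
patient synthetic cohort (seed 1) and write tables to `results/`:

```
python analysis/01_generate_cohort.py     # 21,000 rows incl. duplicates
python analysis/02_preprocess.py          # -> 20,000 clean rows
python analysis/03_describe_thresholds.py
python analysis/04_overall_estimates.py   # neural nuisances, 9 thresholds
python analysis/05_subgroup_grids.py      # 108 subgroup cells, linear nuisances
python analysis/06_simulation_study.py    # coverage + debiasing
```

Preprocessing removes the 1,000 repeat admissions, imputes ~600 missing
cells per lab with the analysis-sample mean, and winsorizes each
continuous variable at its 1st/99th percentiles (TG ends up clipped to
[0.42, 2.98] mmol/L). Thresholds are recomputed within each stratum —
the male TG median is 1.77 mmol/L against the female 1.53 — which is why
every subgroup table carries its own threshold column.

The overall grid (script 04) prints, per decile threshold:

```
percentile  tg_threshold  theta_hat     se   ci_low  ci_high  p_value     n
     0.300         1.390      7.185  0.739    5.735    8.634    0.000 20000
     0.500         1.670      6.516  0.684    5.176    7.856    0.000 20000
     0.700         1.952      6.211  0.741    4.758    7.663    0.000 20000
```

i.e. exceeding the cohort's TG median is associated with a ≈6.5 μmol/L
higher UA after ML adjustment — a weighted blend of the generator's
subgroup effects on the binary-contrast scale, positive and significant
at every threshold. The anemia grid (script 05) resolves the blend:

```
female HGB <=115: n=  290  median theta    0.12  0/9 thresholds p<0.05
female HGB >115 : n= 2492  median theta   12.55  9/9 thresholds p<0.05
male   HGB <=115: n=  283  median theta   -0.27  0/9 thresholds p<0.05
male   HGB >115 : n= 3362  median theta    9.79  9/9 thresholds p<0.05
```

— the anemic 50–65 strata show no TG–UA association at any threshold
while the non-anemic strata are significant at all nine, exactly the
truth the generator encodes. The simulation study (script 06) reports
95.7% CI coverage for the DDML estimator under a linear DGP (300
replicates, n = 2000, θ = 10) and, under strong confounding with a
shrunken ridge nuisance, RMSE 2.6 for DDML against 8.7 for the naive
plug-in, with DDML closer to the truth in 100% of replicates.

A `tgua` CLI wraps the same library calls (`tgua synth`, `preprocess`,
`thresholds`, `estimate`, `grid`, `describe`, `simulate`, `pipeline`);
every artifact records its seed and config hash, and identical seeds
reproduce outputs byte-for-byte.

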