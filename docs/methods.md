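# Methods

## The estimation problem

The package estimates the effect of serum triglycerides (TG, mmol/L) on
serum uric acid (UA, μmol/L) in an inpatient population, under confounding
by demographics and routine labs, and asks how that effect differs across
subgroups — by sex, by age band (≤50, 50–65, >65), and by anemia status
(hemoglobin ≤115 g/L) within the 50–65 band. The exposure is analysed two
ways: dichotomized at each decile of the TG distribution (1 = strictly
above the threshold), which is how the heterogeneity grids are built, and
as the raw continuous value, which is how the simulation studies are run
(so the generator's known coefficient is exactly the estimand).

## Partially linear DDML

The model is the partially linear regression

    UA = θ·D + g(X) + ε,   D = m(X) + ν,

with θ the scalar effect of interest and g, m unrestricted functions of
the covariates X (sex, age, GLU, CREA, CHE, CKMB, HGB by default; sodium
is excluded from adjustment sets but carried in the data). Estimation is
double/debiased machine learning with the partialling-out score:

1. **Cross-fitted nuisances.** The sample is split into K folds (default
   K = 5, sizes differing by at most one). For each fold, learners for
   ℓ(X) = E[UA|X] and m(X) = E[D|X] are trained on the complementary
   folds and predict into the fold, so every residual is out-of-fold.
2. **Orthogonal score.** With u = UA − ℓ̂(X) and v = D − m̂(X), pooled
   across folds ("DML2"),

       θ̂ = Σ vᵢuᵢ / Σ vᵢ²,
       ψᵢ = vᵢ(uᵢ − θ̂vᵢ),
       Var(θ̂) = mean(ψ²) / (n · mean(v²)²).

   The empirical mean of ψ at θ̂ is identically zero (the score is solved
   exactly), and the score is Neyman-orthogonal: first-order errors in
   ℓ̂ or m̂ do not propagate into θ̂. Inference is z-based; 95% CIs use
   z₀.₉₇₅ = 1.959964. A per-fold-averaged variant (solve per fold,
   average) is available; pooled is the default because it is more stable
   at moderate subgroup sizes.

The source text describing the two stages is schematic ("η̂(X) = ML
estimation (X)", "θ̂ = E[Y − η̂X|D]"), so the package implements the
standard partialling-out score of the partially-linear DDML framework;
the IV-type score (residualising Y only on ℓ̂ and instrumenting with v)
is the main alternative reading and is not implemented.

**Learners.** "linear" is OLS; "ridge" standardizes X and applies an L2
penalty (grid over α); "neural" is a single-hidden-layer MLP (lbfgs,
standardized inputs and target, seeded initialisation, fixed cap of 150
iterations) with a grid over width {8, 32, 64} × penalty {1e-4, 1e-2}.
Hyperparameters are picked once per fit by 5-fold CV minimising squared
error, ties to the earlier grid point, then the chosen point is refit in
every cross-fitting fold. For samples above 2000 rows the CV runs on a
seeded subsample of 2000 — the ranking of a six-point grid stabilises far
sooner than the fits themselves, and this keeps neural runs tractable.
For a binary D the m̂ predictions are clipped to [0.01, 0.99] to protect
the score's denominator.

**Naive plug-in baseline.** Fit E[UA|X] on the full sample with the same
(regularised) learner, then regress UA − ℓ̂(X) on raw D with an
intercept. No orthogonalisation, no cross-fitting: whatever part of g(X)
the regularised fit leaves behind and is correlated with D goes straight
into the slope. It exists purely as the comparison showing what the
orthogonal score buys.

**Seeding.** Every run consumes one user seed, split deterministically
(via `SeedSequence` over crc32-hashed labels) into fold-assignment,
CV, and learner-initialisation streams; grid cells derive their seeds
from the base seed plus the cell's labels, so results are invariant to
the order subgroups are listed in. All derived seeds stay below 2³¹.

## Preprocessing protocol

In order: (1) drop records missing UA, TG, sex or age; (2) keep only the
minimal `record_index` per patient (the initial admission); (3) fill
missing lab covariates with the covariate's mean over the post-exclusion
analysis sample (UA/TG are never imputed); (4) winsorize UA, TG, GLU,
CREA, CHE, CKMB, HGB, sodium at their 1st/99th percentiles. Quantiles
everywhere — winsor bounds and TG thresholds alike — use linear
interpolation between order statistics.

Choices worth flagging:

- Imputation means come from the full analysis sample, not per
  cross-fitting fold. That is where a data-selection protocol computes
  them, but it leaks a small amount of information across folds; at the
  sample sizes used here the effect on θ̂ is negligible.
- Winsorization precedes threshold computation, so percentile treatments
  are defined on cleaned data. Descriptives are computed on the
  winsorized table too.
- Winsorization with interpolated quantiles is idempotent only up to the
  interpolation step at the boundary order statistics: a second pass can
  move the clipped tail cells by ~1% of the spacing between extreme
  order statistics. The test suite bounds this rather than asserting
  exact equality.
- Ties at a TG threshold code 0 (treatment means *strictly* exceeding
  the threshold).

## The synthetic cohort generator

No patient data ship with the package; the generator emulates the
structure of a large inpatient laboratory extract:

- **Demographics.** Sex male with probability 0.577; age bands ≤50 /
  50–65 / >65 with weights 0.3744 / 0.3176 / 0.3080 and uniform age
  within band (18–50, 50–65, 65–95). Age is drawn independently of sex.
- **Labs.** Sex-specific normal centers for GLU (8.13/7.92 mmol/L), CREA
  (93.91/72.92 μmol/L), CHE (7701.89/7603.14 U/L), sodium
  (141.06/141.03 mmol/L); CKMB lognormal with median 2 ng/ml and log-sd
  0.9; HGB a two-component mixture — anemic (rate 0.085) centered at
  99.23/102.65 g/L, non-anemic at 148.67/136.13 g/L. The centers are the
  published sex-specific means of the reference cohort; the dispersions,
  the anemia rate applied uniformly across ages, and the mixture form
  are package choices (the source reports no SDs or prevalences).
- **Exposure.** TG = m(X) + ν, m(X) = sex center (1.76/1.53 mmol/L) +
  0.05·(GLU − sex mean), ν ~ N(0, 0.5), floored at 0.1 mmol/L. Glucose
  is thus the confounding channel: it moves both TG and UA.
- **Outcome.** UA = θ(subgroup)·TG + g(X) + ε, ε ~ N(0, 45), floored at
  50 μmol/L. g is additive: linear terms in GLU, HGB, CHE plus — in the
  default "additive-nonlinear" shape — a quadratic in age, a saturating
  tanh in CREA and a log in CKMB (replaced by linear terms under
  `g_shape="linear"`). g also contains −θ(subgroup)·m(X), which centers
  E[UA|X] at the configured sex base (385.23/316.98 μmol/L) regardless
  of θ. θ(subgroup) is a lookup over (sex, age band, HGB band); the
  default map sets 10 in ≤50, 6 in >65, and in 50–65 the headline
  contrast: 0 if anemic, 15 if not.
- **Messiness.** 5% of patients get a second, re-noised admission
  (`record_index = 2`); 1% of rows get one of UA/TG/CREA multiplied by
  Uniform[3, 6]; each lab covariate then goes missing completely at
  random at 3%. UA, TG, sex and age never go missing, matching the
  exclusion rule upstream.

A deliberate design point: the nonlinear pieces of g act on covariates
(age, CREA, CKMB) that do not enter m(X). Linear nuisance learners are
therefore unbiased for this DGP (their misfit is orthogonal to the
treatment residual), which is what lets the 48-cell subgroup grids run
with linear learners at tolerable cost, while the neural learners are
still exercised — and needed for efficiency — on the nonlinear outcome
surface. The `confounded_dgp` used in the debiasing study breaks this
separation on purpose: it boosts the glucose coefficient in g to 30 and
the TG–glucose slope to 0.15 with noise sd 20, so a ridge fit with a
fixed strong penalty (α = 100) leaves a first-order bias that the plug-in
inherits and the orthogonal score does not.

What the generator does **not** emulate: correlated lab panels beyond the
glucose channel, informative (non-MCAR) missingness, age–sex dependence,
longitudinal structure in repeat admissions, or the real cohort's joint
distribution. Passing tests show the estimator and pipeline behave
correctly under a known partially linear truth with realistic marginals
and messiness — they say nothing about effect sizes in any real
population, and no printed coefficient from the reference study is a
target of this package.

## Problem sizes

Defaults were sized so the full test suite and the reproduction script
each run in minutes on one core: effect recovery uses 20 seeds × n = 5000
with neural learners; CI coverage 500 replicates × n = 2000 with linear
learners; debiasing 200 replicates × n = 1000; the anemia-contrast check
20 end-to-end runs at n = 20,000 with linear learners (anemic cells hold
roughly 250–330 patients each, comfortably above the 10-rows-per-fold
floor below which a grid cell is skipped). The analysis scripts use a
single n = 20,000 cohort and neural learners only for the 9-cell overall
grid.

## Known limitations

- Only the partialling-out score is implemented; no IV-type score, no
  CATE/interactive scores, no clustered or bootstrap standard errors.
- E[D|X] for binary D is fit by regression, not a calibrated classifier;
  clipping at [0.01, 0.99] is a blunt guard.
- The anemia subgroup of a record is defined by its realized (possibly
  imputed) HGB, so MCAR missingness causes a small amount of stratum
  misclassification — about 3% of anemic rows land in the non-anemic
  stratum, diluting its contrast negligibly at default rates.
- Multiple testing across the 36–48 grid cells is deliberately not
  adjusted (each cell is reported with its own two-sided p; the
  convention flags p < 0.05), so a handful of false flags per grid is
  expected under the null.
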