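# Methods

## What the package computes

The pipeline compares two survival-prediction models — an unregularized Cox
proportional-hazards fit and a random survival forest (RSF) — across three
feature sets (`Clinical_Only`, `Clinical_PAM` = clinical + expression-derived
subtype, `Clinical_Gene` = clinical + Relief-selected gene features) at 5-,
10- and 15-year landmark horizons, scoring each by an area-based concordance
index under 5-fold cross-validation. All experiments run on synthetic
cohorts with planted, known signal.

## The synthetic cohort generator

The generator emulates the *shape and statistical structure* of a large
breast-cancer registry with expression profiling, not any particular data
set's values.

**Survival model.** Event times follow a proportional-hazards Weibull
(exponential at the default shape 1): the cumulative hazard is
(b·t)^k · e^η with baseline hazard b (default 1/3000 per day, putting the
median event time near 5.7 years at η = 0) and log relative hazard

η = Σ clinical level effects + Σ γ_g z_g + Σ δ · z_a z_b ,

where z_g is the standardized expression of an informative gene. Censoring
is the minimum of an exponential dropout time (default hazard 1/5000 per
day, ≈30% censored within five years) and an administrative cutoff (default
20 years); `status` is `dead` only when the event time comes first.

**Clinical covariates** are sampled categoricals whose levels mirror
standard registry codings (age bands, tumour-size ranges, positive-node
groups, grade, ER status, adjuvant-treatment combinations) with fixed,
roughly realistic marginals; a Nottingham-Prognostic-Index-style composite
is computed from size, nodes and grade. Default level effects follow
standard prognosis directions with hazard ratios of about 1.7–3 for grade 3,
large tumours and heavy nodal burden.

**Informative genes are bimodal.** Background genes are unimodal Gaussians
on a log-intensity-like scale; the planted informative genes are drawn from
a two-component mixture (modes at μ ± 1.2 σ, within-mode σ of 0.6 σ). This
mirrors the bimodal, subtype-driven distributions typical of prognostic
marker genes — and it matters methodologically: equal-width three-bin
discretization of a *unimodal* Gaussian puts roughly three quarters of
patients into the middle bin and erases most of the signal before feature
selection ever sees it, whereas the bins of a bimodal gene separate the two
modes. Defaults: 8 informative genes among 200, alternating coefficients
±0.6 per standardized unit, and four disjoint product interactions with
coefficient 0.8. The interaction terms are marginally uncorrelated with
their factors, so they plant a purely non-linear signal that a main-effects
Cox model cannot represent — the synthetic analogue of the forest's
advantage on real tumour data.

**Subtype label.** `Pam50_subtype` is a coarse deterministic function
(quadrant of the first two informative genes' standardized values, with a
near-zero "Normal" band), reflecting that a molecular subtype is itself a
composite of expression data. `Clinical_Only` therefore excludes it;
`Clinical_PAM` includes it.

**What the generator does not emulate:** realistic gene–gene correlation
beyond the planted effects, copy-number features, non-proportional hazards,
informative censoring, cohort heterogeneity across collection sites.
Passing tests show the machinery is correct and that the directional
findings hold under a known planted truth; they say nothing about effect
sizes on real tumours.

## Preprocessing

- **Discretization**: per-feature equal width over [min, max] into M = 3
  ordered bins labelled low/medium/high; the maximum is capped into the top
  bin; a constant feature is flagged degenerate and mapped to "low". During
  cross-validation, bin edges come from the training folds and are applied
  to the held-out fold (out-of-range values clip into the end bins).
- **Imputation**: categorical cells take the training-fold mode (ties break
  to the earliest level in category order), numeric cells the median;
  deterministic by construction. A fully missing column is an error.
- **Year table**: the event-or-last-contact year is ⌈day/365⌉. A patient
  who died in year e is `alive` before e and `dead` from e on; a censored
  patient is `alive` through the year last seen and `NA` afterwards. The
  landmark target at year Y is that column; `NA` patients are dropped from
  Relief's input (it needs a binary target) but kept for model fitting,
  which handles censoring natively.

## Relief

The sampled algorithm draws m items with replacement (m defaults to the
number of items) and updates W[F] by −Diff(F,D,H)/m + Diff(F,D,M)/m, with
Diff the 0/1 same-value indicator, H/M the nearest same/other-class items
under Hamming distance over all features (self excluded; distance ties break
to the lowest index). Weights are bounded in [−1, 1]. Because the target
must be binary, each class must contain at least two items (otherwise no
nearest hit exists). `relief_rank_exhaustive` visits every item exactly once
and divides by n; it is deterministic, the sampled weights are unbiased for
it, and it serves as the oracle in tests. The full ReliefF generalization
(k nearest neighbours, multi-class targets, missing-value handling) is
deliberately not implemented: the pipeline operates on imputed data with
binary landmark targets, where plain Relief is the applicable case.

A practical note from the package's own experiments: 1-nearest-neighbour
Relief in a several-hundred-dimensional Hamming space is noisy; with 500
background genes and n ≈ 300 it recovers strong planted drivers well above
chance but not exhaustively (mean recall around 0.6–0.7 in the regression
test, whose threshold of 0.5 was frozen after a single pilot run).

**Method 1** ranks clinical + gene features together and keeps the top k.
**Method 2** ranks genes alone, keeps the top k − n_clinical, and adds every
clinical feature, so the total is still k. The default feature-count grid is
k ∈ {30, 50, 100, 150}.

## Cox model

Breslow-tie partial likelihood maximized by Newton–Raphson with step
halving; convergence when the largest score component falls below 1e−6,
at most 50 iterations; non-convergence and divergence (|β| > 50) raise an
error carrying the iteration trace. Categorical covariates are one-hot
encoded against the most frequent training level; constant design columns
are dropped and recorded. Follow-up is administratively censored at the
horizon before fitting, so a Y-year model sees only the first Y years of
information. The baseline cumulative hazard is the Breslow estimator on the
distinct event times, and predictions are right-continuous step curves
S(t) = exp(−Λ₀(t)·e^{xβ}) with constant extrapolation to the horizon.
No shrinkage of any kind is applied — on purpose, since the degradation of
an unpenalized Cox fit as encoded covariates multiply is one of the
phenomena under study.

## Random survival forest

Per tree: a bootstrap resample of the cohort (≈37% of patients excluded on
average), recursive node splitting among ⌈√p⌉ randomly drawn candidate
covariates (configurable), choosing the split that maximizes the two-sample
log-rank statistic (O−E)²/V between daughters. Ordered covariates (the
low/medium/high gene levels, ordinal clinical bins) split by level
threshold; unordered covariates split one level against the rest. A split
is admissible only if both daughters keep at least D = 3 distinct death
times (configurable); a node with no admissible split becomes a leaf with
the Nelson–Aalen cumulative hazard of its patients. Prediction routes a
patient down every tree (an unseen level follows the daughter that received
the majority of training rows) and averages leaf CHFs on the grid of
training event times; out-of-bag curves average only trees whose bootstrap
missed the patient, and patients in-bag everywhere are excluded from the
out-of-bag estimate. The default of 500 trees is conventional; the test
suite and acceptance script use 100 trees, which pilot runs showed is where
the out-of-bag and cross-validated concordances have stabilized at the
cohort sizes used (n ≤ 500).

## Evaluation

**Area concordance.** Each predicted curve is summarized by its exact step
integral over [0, horizon]. Every patient j dead within the horizon is
paired with every patient k whose observed time (death or censoring) is
strictly later; the pair adds 1 to `Total` only when area_j < area_k
strictly. The index is Total / #pairs. Ties in area score zero — a known
pessimism of the strict rule (two identical predictors score 0, not 0.5),
accepted because the strictness is part of the estimator's definition. An
equal observed time never forms a pair.

**Chi-square comparison.** Two concordance results are compared by a 2×2
chi-square test (no continuity correction) on their concordant/discordant
pair counts — the construction consistent with comparing two proportions of
concordant pairs.

**Cross-validation.** Patients are randomly partitioned (seeded) into five
near-equal folds. Every data-dependent step — imputation statistics,
discretization edges, Relief ranking, model fitting — uses the training
folds only; the held-out fold receives predicted curves. Out-of-fold curves
are pooled into one cohort-wide concordance (per-fold indices are also
reported for inspection). One master seed drives fold assignment, and
per-stage seeds are derived from it by fixed offsets.

## Numerical and design choices

- Day-to-year mapping ⌈day/365⌉; death "in" a year means the year containing
  the event day.
- Discretized expression (not raw values) is what the models consume, for
  both Cox and RSF, matching the pipeline's all-categorical design.
- Relief tie-breaks (lowest index) and ranking tie-breaks (column order)
  make every selection deterministic given a seed.
- The exhaustive Relief sweep, the brute-force concordance enumeration, the
  grid-search partial-likelihood maximizer and the step-by-step Nelson–Aalen
  estimator exist as independent oracles in the test suite and are never
  used as the implementation path.
- Problem sizes in tests and the acceptance script (cohorts of 150–500
  patients, 200–500 genes, 10–20 Monte-Carlo seeds, 100-tree forests) were
  chosen as the smallest at which the measured quantities are stable; the
  generator scales to registry-sized cohorts (thousands of patients, tens of
  thousands of genes) for exploratory use.

## Known limitations

- Plain Relief's 1-NN neighbourhoods limit selection power in very high
  dimensions; a k-NN ReliefF variant would be the natural extension.
- The chi-square comparison treats pooled pair counts as independent
  observations, which overstates certainty when the same patients appear in
  many pairs; it is used here as a comparison statistic, not a calibrated
  test.
- Absolute concordance values on synthetic cohorts depend on the planted
  effect sizes and are not comparable to values on any real registry; only
  the directional comparisons are meaningful.
- The Cox fit computes an O(n·p²) cumulative term per Newton iteration;
  beyond a few hundred encoded columns it becomes the pipeline's memory
  bottleneck.
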