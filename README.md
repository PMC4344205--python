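# survcompare

Tools for asking a question that matters in breast-cancer prognosis: **does
high-dimensional gene-expression data improve survival prediction beyond a
complete set of clinical covariates, and does a random survival forest beat
the Cox model at that task?**

The package is aimed at biostatisticians and methods researchers who want the
full comparison machinery — not a single model fit — as tested, reusable
code:

- a **synthetic cohort generator** that emulates a METABRIC-like resource
  (categorical clinical covariates, a patients × genes expression matrix with
  a small planted informative subset, right-censored follow-up, an
  expression-derived subtype label) with known ground truth, so every stage
  is testable without access-controlled data;
- **preprocessing**: equal-width discretization of expression into
  low/medium/high (M = 3), mode/median imputation, and the per-year
  alive/dead/NA grid that makes right censoring explicit, from which binary
  landmark targets (survivorship at year Y) are read off;
- **Relief feature selection** over clinical + gene features, with the
  deterministic exhaustive sweep as a built-in oracle and the two
  integration schemes (rank everything together, or rank genes only and add
  all clinical features);
- an **unregularized Cox proportional-hazards model** fit by Newton–Raphson
  on the Breslow partial likelihood, with Breslow baseline hazard and
  per-patient survival step curves;
- a **random survival forest**: bootstrap trees, log-rank splitting,
  unique-death stopping, Nelson–Aalen leaf cumulative hazards, ensemble CHF
  averaging, and out-of-bag error;
- an **area-based concordance index** (pair each patient who died with every
  patient observed longer; count strict `area_j < area_k`), a chi-square
  comparison of two concordance results, and a 5-fold cross-validation
  harness over the data-set variants `Clinical_Only`, `Clinical_PAM` and
  `Clinical_Gene`.

## The model in brief

Survival follows a proportional-hazards law λ(t|x) = λ₀(t)·exp(xβ). The Cox
model estimates β by maximizing the partial likelihood and predicts
S(t|x) = exp(−Λ₀(t)·e^{xβ}). The forest instead grows M bootstrap trees,
splitting each node on the candidate covariate/level-set that maximizes the
two-sample log-rank statistic between daughters, stopping when a split would
leave a daughter with fewer than D distinct death times; each leaf carries a
Nelson–Aalen cumulative hazard, prediction averages leaf CHFs across trees,
and each bootstrap's ~37% excluded patients give an out-of-bag error.
Predictions are compared by the concordance index C = Total / #pairs, where a
pair (j dead, k observed strictly later) scores 1 iff j's survival-curve area
is strictly smaller than k's.

## Worked example

```python
import numpy as np
from survcompare import (CohortSpec, RSFConfig, generate_cohort,
                         cross_validate, compare_concordance_chisq)

cohort = generate_cohort(CohortSpec(seed=0))
print(f"cohort: {len(cohort)} patients, {cohort.expression.shape[1]} genes, "
      f"{(cohort.status == 'dead').mean():.0%} deceased")

cfg = RSFConfig(n_trees=100, seed=0)
cox  = cross_validate(cohort, "Clinical_Gene", "cox", year=5, k=30, method=2, seed=0)
rsf  = cross_validate(cohort, "Clinical_Gene", "rsf", year=5, k=30, method=2,
                      seed=0, rsf_config=cfg)
base = cross_validate(cohort, "Clinical_Only", "rsf", year=5, seed=0, rsf_config=cfg)
print(f"Clinical_Gene / Cox  concordance: {cox.index:.3f}  (Total={cox.total}, pairs={cox.n_pairs})")
print(f"Clinical_Gene / RSF  concordance: {rsf.index:.3f}  (Total={rsf.total}, pairs={rsf.n_pairs})")
print(f"Clinical_Only / RSF  concordance: {base.index:.3f}")
print(f"chi-square p (RSF vs Cox): {compare_concordance_chisq(rsf, cox):.2e}")
```

prints

```
cohort: 500 patients, 200 genes, 67% deceased
Clinical_Gene / Cox  concordance: 0.582  (Total=57178, pairs=98179)
Clinical_Gene / RSF  concordance: 0.590  (Total=57954, pairs=98179)
Clinical_Only / RSF  concordance: 0.537
chi-square p (RSF vs Cox): 3.77e-04
```

Reading the output: under 5-fold cross-validation at the 5-year horizon, the
forest given clinical + selected gene features orders patient pairs correctly
59.0% of the time, beating both the unregularized Cox model on the same
features (58.2%, a difference the pairwise chi-square test calls significant)
and the forest restricted to clinical covariates only (53.7%) — the two
directional findings the package exists to study, here reproduced on a
cohort whose planted gene effects and interactions are known exactly.

The same pipeline is scriptable from the shell:

```bash
survcompare generate --seed 0 --out cohort/
survcompare run-grid --cohort cohort/ --config grid.json --seed 0 --out results/
```

## Layout

```
src/survcompare/
  synthetic_cohort.py   cohort generator + CSV round-trip
  preprocess.py         discretization, imputation, year table, landmarks
  relief_selection.py   Relief weights, exhaustive oracle, Method 1/2
  cox_model.py          partial-likelihood Cox + Breslow baseline
  rsf_model.py          random survival forest + out-of-bag error
  evaluation.py         area concordance, chi-square, CV, experiment grid
  curves.py             survival step curves
  cli.py                `survcompare` command-line front end
docs/methods.md         modelling assumptions, defaults, limitations
```
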