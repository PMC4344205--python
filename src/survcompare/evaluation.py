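"""Concordance evaluation, model comparison, and the cross-validated grid.

The concordance estimator is area-based: each patient's predicted survival
curve is summarized by its area under the curve over the horizon; patient
``j``, known to die, is paired with every patient ``k`` whose observed time
(death or censoring) is strictly later, and a pair counts as concordant
(adds 1 to ``Total``) only when ``area_j < area_k`` strictly.  The index is
``Total / n_pairs``.  Two concordance results are compared with a 2x2
chi-square test on their concordant/discordant counts.

``cross_validate`` runs the full pipeline — imputation, discretization,
Relief selection and model fitting, all on the training folds only — and
pools the out-of-fold curves into a single cohort-wide concordance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import relief_selection
from .cox_model import fit_cox, predict_survival_curves
from .curves import StepCurve
from .preprocess import NA, build_year_table, discretize_frame, impute_clinical, landmark_target
from .rsf_model import RSFConfig, fit_rsf, predict_survival_curves_rsf
from .synthetic_cohort import SUBTYPE_COLUMN, Cohort

__all__ = [
    "ConcordanceResult",
    "ExperimentGrid",
    "EvaluationError",
    "survival_curve_area",
    "concordance_index",
    "compare_concordance_chisq",
    "cross_validate",
    "run_experiment",
    "VARIANTS",
]

VARIANTS = ("Clinical_Only", "Clinical_PAM", "Clinical_Gene")
DAYS_PER_YEAR = 365


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance index = total (concordant pairs) / n_pairs (evaluable)."""

    index: float
    total: int
    n_pairs: int
    fold_indices: tuple[float, ...] | None = None


def survival_curve_area(curve: StepCurve, horizon: float) -> float:
    """Exact area under a survival step curve over [0, horizon]."""
    return curve.area(horizon)


def concordance_index(curves, day, status, horizon: float) -> ConcordanceResult:
    """Area-based concordance over all evaluable patient pairs.

    ``j`` ranges over patients dead within the horizon; ``k`` over patients
    with observed time strictly later than ``j``'s death (whether ``k``'s
    time is a death or a censoring time).  ``Total`` counts strict
    ``area_j < area_k``; ties contribute nothing.
    """
    day = np.asarray(day, dtype=float)
    status = np.asarray(status, dtype=object)
    areas = np.array([c.area(horizon) for c in curves])
    if len(areas) != len(day):
        raise EvaluationError("one curve per patient required")
    dead_j = (status == "dead") & (day <= horizon)
    later = day[None, :] > day[:, None]  # later[j, k]: k observed after j
    pair = dead_j[:, None] & later
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        raise EvaluationError("no evaluable pairs")
    total = int((pair & (areas[:, None] < areas[None, :])).sum())
    return ConcordanceResult(index=total / n_pairs, total=total, n_pairs=n_pairs)


def compare_concordance_chisq(a: ConcordanceResult, b: ConcordanceResult) -> float:
    """Chi-square p-value for the 2x2 concordant/discordant table of two
    methods (no continuity correction)."""
    table = np.array(
        [[a.total, a.n_pairs - a.total], [b.total, b.n_pairs - b.total]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise EvaluationError("degenerate contingency table (zero row or column)")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(p)


# --- cross-validation harness ----------------------------------------------

def _fold_assignments(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _variant_clinical(cohort: Cohort, variant: str) -> pd.DataFrame:
    if variant not in VARIANTS:
        raise EvaluationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    clin = cohort.clinical
    if variant == "Clinical_PAM":
        return clin
    return clin.drop(columns=[SUBTYPE_COLUMN])


def cross_validate(
    cohort: Cohort,
    variant: str,
    model: str,
    year: int,
    k: int | None = None,
    method: int | None = None,
    folds: int = 5,
    seed: int = 0,
    rsf_config: RSFConfig | None = None,
    relief_m: int | None = None,
) -> ConcordanceResult:
    """Pooled out-of-fold concordance for one grid cell.

    Per fold, every data-dependent step — imputation statistics,
    discretization edges, Relief ranking, model fitting — uses the training
    folds only.  For ``Clinical_Gene``, Relief selects ``k`` features by
    Method 1 (clinical and genes ranked together) or Method 2 (genes ranked
    alone, then all clinical features added); the Relief target is
    survivorship at the landmark ``year``, with patients censored before the
    landmark excluded from the ranking (but kept for model fitting, which
    handles censoring natively).
    """
    if model not in ("cox", "rsf"):
        raise EvaluationError(f"unknown model {model!r}")
    if variant == "Clinical_Gene":
        if k is None or method not in (1, 2):
            raise EvaluationError("Clinical_Gene needs k and method in {1, 2}")
    n = len(cohort)
    if n < folds:
        raise EvaluationError("cohort smaller than the number of folds")
    horizon = year * DAYS_PER_YEAR
    rng = np.random.default_rng(seed)
    fold_idx = _fold_assignments(n, folds, rng)
    clin_all = _variant_clinical(cohort, variant)
    day = cohort.day
    status = cohort.status

    curves: list[StepCurve | None] = [None] * n
    fold_results = []
    for f, te in enumerate(fold_idx):
        tr = np.sort(np.setdiff1d(np.arange(n), te))
        if not np.any((status[tr] == "dead") & (day[tr] <= horizon)):
            raise EvaluationError(f"training folds for fold {f} contain no events")
        clin_tr = impute_clinical(clin_all.iloc[tr])
        clin_te = impute_clinical(clin_all.iloc[te], reference=clin_all.iloc[tr])

        if variant == "Clinical_Gene":
            disc_tr = discretize_frame(cohort.expression.iloc[tr])
            disc_te = discretize_frame(cohort.expression.iloc[te], fit=disc_tr)
            ytab = build_year_table(day[tr], status[tr], horizon_years=year)
            target = landmark_target(ytab, year)
            keep = (target != NA).to_numpy()
            relief_seed = int((seed * 97 + f) % 2**31)
            if method == 1:
                combined = pd.concat(
                    [clin_tr.reset_index(drop=True), disc_tr.data.reset_index(drop=True)],
                    axis=1,
                )
                selected = relief_selection.method1_select(
                    combined.loc[keep], target[keep], k, m=relief_m, seed=relief_seed
                )
            else:
                selected = relief_selection.method2_select(
                    disc_tr.data.reset_index(drop=True).loc[keep],
                    target[keep],
                    k,
                    list(clin_tr.columns),
                    m=relief_m,
                    seed=relief_seed,
                )
            all_tr = pd.concat(
                [clin_tr.reset_index(drop=True), disc_tr.data.reset_index(drop=True)], axis=1
            )
            all_te = pd.concat(
                [clin_te.reset_index(drop=True), disc_te.data.reset_index(drop=True)], axis=1
            )
            feats_tr, feats_te = all_tr[selected], all_te[selected]
        else:
            feats_tr = clin_tr.reset_index(drop=True)
            feats_te = clin_te.reset_index(drop=True)

        if model == "cox":
            fit = fit_cox(feats_tr, day[tr], status[tr], horizon=horizon)
            fold_curves = predict_survival_curves(fit, feats_te, horizon)
        else:
            cfg = rsf_config or RSFConfig()
            cfg = RSFConfig(
                n_trees=cfg.n_trees,
                n_candidates=cfg.n_candidates,
                min_unique_deaths=cfg.min_unique_deaths,
                seed=int((cfg.seed * 31 + seed * 97 + f) % 2**31),
            )
            fit = fit_rsf(feats_tr, day[tr], status[tr], horizon=horizon, config=cfg)
            fold_curves = predict_survival_curves_rsf(fit, feats_te, horizon)
        for pos, c in zip(te, fold_curves):
            curves[pos] = c
        try:
            fold_results.append(
                concordance_index(fold_curves, day[te], status[te], horizon).index
            )
        except EvaluationError:
            fold_results.append(float("nan"))

    pooled = concordance_index(curves, day, status, horizon)
    return ConcordanceResult(
        index=pooled.index,
        total=pooled.total,
        n_pairs=pooled.n_pairs,
        fold_indices=tuple(fold_results),
    )


# --- experiment grid --------------------------------------------------------

@dataclass(frozen=True)
class ExperimentGrid:
    """The full comparison grid: data variants x models x landmark years,
    with the Relief feature-count grid and both integration methods for the
    gene-expression variant."""

    variants: tuple[str, ...] = VARIANTS
    models: tuple[str, ...] = ("cox", "rsf")
    years: tuple[int, ...] = (5, 10, 15)
    ks: tuple[int, ...] = (30, 50, 100, 150)
    methods: tuple[int, ...] = (1, 2)
    folds: int = 5
    seed: int = 0
    rsf_config: RSFConfig = field(default_factory=RSFConfig)


def run_experiment(cohort: Cohort, grid: ExperimentGrid) -> dict:
    """Run every grid cell; return the result table and the comparisons.

    Returns ``{"results": DataFrame, "comparisons": DataFrame}``.  The
    results table has one row per (variant, model, year[, method, k]) with
    the pooled concordance, ``Total`` and pair count.  Comparisons hold the
    chi-square p-values for (a) Cox vs RSF per variant and year (each model
    at its best feature count) and (b) each gene-bearing variant vs
    Clinical_Only per year, best over models and feature counts.
    """
    rows = []
    store: dict[tuple, ConcordanceResult] = {}
    for variant, model, year in itertools.product(grid.variants, grid.models, grid.years):
        cells = (
            [(mth, k) for mth in grid.methods for k in grid.ks]
            if variant == "Clinical_Gene"
            else [(None, None)]
        )
        for method, k in cells:
            res = cross_validate(
                cohort,
                variant,
                model,
                year,
                k=k,
                method=method,
                folds=grid.folds,
                seed=grid.seed,
                rsf_config=grid.rsf_config,
            )
            store[(variant, model, year, method, k)] = res
            rows.append(
                {
                    "variant": variant,
                    "model": model,
                    "year": year,
                    "method": method,
                    "k": k,
                    "concordance": res.index,
                    "total": res.total,
                    "n_pairs": res.n_pairs,
                }
            )
    results = pd.DataFrame(rows)

    def best(variant, year, models):
        cands = [
            (key, res)
            for key, res in store.items()
            if key[0] == variant and key[2] == year and key[1] in models
        ]
        return max(cands, key=lambda kv: kv[1].index)

    comparisons = []
    for variant, year in itertools.product(grid.variants, grid.years):
        if all(m in grid.models for m in ("cox", "rsf")):
            (kc, rc), (kr, rr) = best(variant, year, {"cox"}), best(variant, year, {"rsf"})
            comparisons.append(
                {
                    "comparison": "cox_vs_rsf",
                    "variant": variant,
                    "year": year,
                    "a": f"cox(k={kc[4]})",
                    "b": f"rsf(k={kr[4]})",
                    "index_a": rc.index,
                    "index_b": rr.index,
                    "p_value": compare_concordance_chisq(rc, rr),
                }
            )
    if "Clinical_Only" in grid.variants:
        for variant, year in itertools.product(grid.variants, grid.years):
            if variant == "Clinical_Only":
                continue
            (kv, rv) = best(variant, year, set(grid.models))
            (ko, ro) = best("Clinical_Only", year, set(grid.models))
            comparisons.append(
                {
                    "comparison": "variant_vs_clinical_only",
                    "variant": variant,
                    "year": year,
                    "a": f"{variant}/{kv[1]}(k={kv[4]})",
                    "b": f"Clinical_Only/{ko[1]}",
                    "index_a": rv.index,
                    "index_b": ro.index,
                    "p_value": compare_concordance_chisq(rv, ro),
                }
            )
    return {"results": results, "comparisons": pd.DataFrame(comparisons)}
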