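"""Area concordance, chi-square comparison, and the CV harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from survcompare import (
    CohortSpec,
    StepCurve,
    compare_concordance_chisq,
    concordance_index,
    cross_validate,
    generate_cohort,
    run_experiment,
    survival_curve_area,
)
from survcompare.evaluation import (
    ConcordanceResult,
    EvaluationError,
    ExperimentGrid,
    _fold_assignments,
)
from survcompare.rsf_model import RSFConfig
from conftest import random_step_curve


def brute_force_concordance(areas, day, status, horizon):
    """Independent double-loop pair enumeration of the printed rule."""
    total = pairs = 0
    for j in range(len(day)):
        if status[j] != "dead" or day[j] > horizon:
            continue
        for k in range(len(day)):
            if day[k] > day[j]:
                pairs += 1
                if areas[j] < areas[k]:
                    total += 1
    return total, pairs


class TestArea:
    def test_flat_one_has_area_equal_horizon(self):
        c = StepCurve(times=np.array([]), values=np.array([]))
        assert survival_curve_area(c, 100.0) == 100.0

    def test_drop_to_zero_at_half_horizon(self):
        c = StepCurve(times=np.array([50.0]), values=np.array([0.0]))
        assert survival_curve_area(c, 100.0) == 50.0

    def test_single_baseline_step_closed_form(self):
        # Cox-style curve: one hazard step h at t1 -> area t1 + (H - t1) e^{-h}
        t1, h, H = 30.0, 0.8, 100.0
        c = StepCurve(times=np.array([t1]), values=np.array([np.exp(-h)]))
        assert survival_curve_area(c, H) == pytest.approx(t1 + (H - t1) * np.exp(-h))

    def test_increasing_curve_rejected(self):
        c = StepCurve(times=np.array([1.0, 2.0]), values=np.array([0.5, 0.9]))
        with pytest.raises(ValueError):
            survival_curve_area(c, 10.0)


class TestConcordance:
    def test_three_deaths_with_concordant_areas(self):
        day = np.array([100.0, 200.0, 300.0])
        status = np.array(["dead"] * 3, dtype=object)
        curves = [
            StepCurve(times=np.array([t]), values=np.array([0.0])) for t in (50.0, 150.0, 250.0)
        ]
        res = concordance_index(curves, day, status, horizon=400.0)
        assert (res.index, res.total, res.n_pairs) == (1.0, 3, 3)

    def test_identical_curves_score_zero_under_strict_rule(self):
        day = np.array([100.0, 200.0, 300.0])
        status = np.array(["dead"] * 3, dtype=object)
        curves = [StepCurve(times=np.array([10.0]), values=np.array([0.5]))] * 3
        res = concordance_index(curves, day, status, horizon=400.0)
        assert res.total == 0 and res.index == 0.0

    def test_anticoncordant_areas_score_zero(self):
        day = np.array([100.0, 200.0, 300.0])
        status = np.array(["dead"] * 3, dtype=object)
        curves = [
            StepCurve(times=np.array([t]), values=np.array([0.0])) for t in (250.0, 150.0, 50.0)
        ]
        assert concordance_index(curves, day, status, horizon=400.0).index == 0.0

    def test_patient_censored_before_first_death_joins_no_pair(self):
        day = np.array([50.0, 100.0, 200.0])
        status = np.array(["alive", "dead", "dead"], dtype=object)
        curves = [random_step_curve(np.random.default_rng(i), 300.0) for i in range(3)]
        res = concordance_index(curves, day, status, horizon=300.0)
        # pairs: (1, 2) only from j=1; j=2 has no later patient
        assert res.n_pairs == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            day = rng.uniform(1, 1000, n)
            status = np.where(rng.random(n) < 0.6, "dead", "alive").astype(object)
            if not ((status == "dead") & (day <= 800)).any():
                status[0], day[0] = "dead", 100.0
            curves = [random_step_curve(rng, 1000.0) for _ in range(n)]
            res = concordance_index(curves, day, status, horizon=800.0)
            areas = [c.area(800.0) for c in curves]
            total, pairs = brute_force_concordance(areas, day, status, 800.0)
            assert (res.total, res.n_pairs) == (total, pairs)

    def test_no_evaluable_pairs_is_an_error(self):
        day = np.array([100.0])
        status = np.array(["dead"], dtype=object)
        with pytest.raises(EvaluationError):
            concordance_index([random_step_curve(np.random.default_rng(0), 300.0)], day, status, 300.0)


class TestChiSquare:
    def test_identical_counts_give_p_one(self):
        a = ConcordanceResult(index=0.8, total=800, n_pairs=1000)
        assert compare_concordance_chisq(a, a) == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # table [[900,100],[500,500]]: E = [[700,300],[700,300]],
        # X^2 = 200^2 (1/700 + 1/300 + 1/700 + 1/300) = 2742.857/7.2 -> 380.95
        a = ConcordanceResult(index=0.9, total=900, n_pairs=1000)
        b = ConcordanceResult(index=0.5, total=500, n_pairs=1000)
        stat = 200**2 * (2 / 700 + 2 / 300)
        assert compare_concordance_chisq(a, b) == pytest.approx(chi2.sf(stat, df=1))

    def test_symmetric_in_arguments(self):
        a = ConcordanceResult(index=0.7, total=700, n_pairs=1000)
        b = ConcordanceResult(index=0.6, total=540, n_pairs=900)
        assert compare_concordance_chisq(a, b) == compare_concordance_chisq(b, a)

    def test_zero_margin_is_an_error(self):
        a = ConcordanceResult(index=1.0, total=100, n_pairs=100)
        with pytest.raises(EvaluationError):
            compare_concordance_chisq(a, a)


class TestCrossValidation:
    def test_fold_sizes_differ_by_at_most_one(self):
        for n in (101, 1981, 55):
            folds = _fold_assignments(n, 5, np.random.default_rng(0))
            sizes = [len(f) for f in folds]
            assert sum(sizes) == n and max(sizes) - min(sizes) <= 1
            assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(n))

    def test_same_seed_reproduces_result(self, small_cohort):
        r1 = cross_validate(small_cohort, "Clinical_Only", "cox", 5, seed=3)
        r2 = cross_validate(small_cohort, "Clinical_Only", "cox", 5, seed=3)
        assert r1 == r2
        assert 0.0 <= r1.index <= 1.0
        assert len(r1.fold_indices) == 5

    def test_training_fold_without_events_is_identified(self):
        spec = CohortSpec(n_patients=40, n_genes=5, n_informative_genes=2,
                          gene_effects=[0.0, 0.0], seed=0)
        cohort = generate_cohort(spec)
        cohort.day = np.full(40, 4000.0)
        cohort.status = np.array(["alive"] * 40, dtype=object)
        with pytest.raises(EvaluationError, match="fold"):
            cross_validate(cohort, "Clinical_Only", "cox", 5, seed=0)

    def test_clinical_gene_requires_k_and_method(self, small_cohort):
        with pytest.raises(EvaluationError, match="k and method"):
            cross_validate(small_cohort, "Clinical_Gene", "cox", 5, seed=0)

    def test_zero_signal_concordance_near_chance(self):
        indices = []
        for seed in range(5):
            spec = CohortSpec(n_patients=200, n_genes=5, n_informative_genes=2,
                              clinical_effects={}, gene_effects=[0.0, 0.0],
                              interaction_strength=0.0, seed=seed)
            cohort = generate_cohort(spec)
            indices.append(cross_validate(cohort, "Clinical_Only", "cox", 5, seed=seed).index)
        assert abs(np.mean(indices) - 0.5) < 0.05

    def test_true_risk_feature_never_falls_below_noise_baseline(self):
        """Adding the (binned) true log-hazard as a clinical feature must
        not produce worse concordance than a signal-free model; one-sided
        sign test over 10 seeds."""
        wins = 0
        for seed in range(10):
            spec = CohortSpec(n_patients=150, n_genes=5, n_informative_genes=2,
                              clinical_effects={}, gene_effects=[0.8, -0.8],
                              interaction_strength=0.0, seed=seed)
            cohort = generate_cohort(spec)
            baseline = cross_validate(cohort, "Clinical_Only", "cox", 5, seed=seed).index
            eta = np.asarray(cohort.truth["eta"])
            bins = np.quantile(eta, [0.2, 0.4, 0.6, 0.8])
            risk = pd.Categorical.from_codes(
                np.digitize(eta, bins),
                dtype=pd.CategoricalDtype(["q1", "q2", "q3", "q4", "q5"], ordered=True),
            )
            cohort.clinical = cohort.clinical.assign(true_risk=risk)
            enriched = cross_validate(cohort, "Clinical_Only", "cox", 5, seed=seed).index
            wins += enriched >= baseline
        assert wins >= 9


class TestRunExperiment:
    def test_small_grid_schema_and_ranges(self):
        cohort = generate_cohort(CohortSpec(n_patients=150, n_genes=30, seed=1))
        grid = ExperimentGrid(
            years=(5,), ks=(12,), methods=(1, 2),
            rsf_config=RSFConfig(n_trees=25, seed=0), seed=1,
        )
        out = run_experiment(cohort, grid)
        results = out["results"]
        # 2 models x (Clinical_Only + Clinical_PAM) + 2 models x 2 methods x 1 k
        assert len(results) == 2 * 2 + 2 * 2 * 1
        assert results["concordance"].between(0, 1).all()
        gene_rows = results[results["variant"] == "Clinical_Gene"]
        assert set(gene_rows["method"]) == {1, 2}
        comps = out["comparisons"]
        assert {"cox_vs_rsf", "variant_vs_clinical_only"} <= set(comps["comparison"])
        assert comps["p_value"].between(0, 1).all()
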