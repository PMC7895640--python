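import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from misscase import SimConfig, generate_cohort, simulate
from misscase.missingness import (MissingnessModel, NoContrastError,
                                  SingleClassOutcomeError, auroc_rank,
                                  delong_ci, fit_multivariate, fit_univariate,
                                  nagelkerke_r2, odds_to_probability,
                                  probability_to_odds_ratio,
                                  relative_risk_increment)
from misscase.missingness import \
    test_missingness_interaction as missingness_interaction_test


def two_by_two_cohort(factory, exposed_missing, exposed_obs, unexposed_missing,
                      unexposed_obs):
    records, i = [], 0
    for gender, missing, count in [(1, True, exposed_missing),
                                   (1, False, exposed_obs),
                                   (0, True, unexposed_missing),
                                   (0, False, unexposed_obs)]:
        for _ in range(count):
            records.append({"id": i, "gender": gender,
                            "phq9": (10, 8, None if missing else 6)})
            i += 1
    return factory(records)


class TestUnivariate:
    def test_two_by_two_odds_ratio_cross_product(self, cohort_factory):
        """Saturated 2x2 logistic fit equals the hand-computed cross-product
        odds ratio (3*3)/(1*1) = 9."""
        cohort = two_by_two_cohort(cohort_factory, 3, 1, 1, 3)
        res, _, _ = fit_univariate(cohort, "gender")
        odds = res.odds_ratios()["odds_ratio"].iloc[0]
        assert odds == pytest.approx(9.0, abs=1e-4)

    def test_constant_predictor_rejected(self, cohort_factory):
        cohort = cohort_factory([
            {"id": 0, "gender": 1, "phq9": (10, 8, None)},
            {"id": 1, "gender": 1, "phq9": (10, 8, 6)},
        ])
        with pytest.raises(NoContrastError):
            MissingnessModel(cohort, ["gender"])

    def test_single_class_outcome_rejected(self, cohort_factory):
        cohort = cohort_factory([
            {"id": 0, "gender": 1, "phq9": (10, 8, 6)},
            {"id": 1, "gender": 0, "phq9": (10, 8, 6)},
        ])
        with pytest.raises(SingleClassOutcomeError):
            MissingnessModel(cohort, ["gender"])

    def test_completion_or_recovery_within_generating_ci(self, study_cohort):
        """The fitted 1-of-5 completion OR falls inside the generating
        value's reported CI span (~109-241)."""
        res, cm, risks = fit_univariate(study_cohort, "completion")
        ors = res.odds_ratios()
        one = ors.loc[[i for i in ors.index if "[T.1]" in i][0]]
        assert 109 < one["odds_ratio"] < 241
        by_label = {r.label: r.probability_pct for r in risks}
        assert 90 < by_label["completed 1 of 5"] < 98
        assert by_label["completed all modules"] < 14

    def test_separation_triggers_firth_fallback(self, cohort_factory):
        records = [{"id": i, "gender": 1, "phq9": (10, 8, None)}
                   for i in range(12)]
        records += [{"id": 12 + i, "gender": 0, "phq9": (10, 8, 6)}
                    for i in range(12)]
        cohort = cohort_factory(records)
        res = MissingnessModel(cohort, ["gender"]).fit()
        assert res.method == "firth"
        assert res.separation
        assert res.nagelkerke_r2 > 0.8   # approaches 1 in the limit


class TestNagelkerke:
    def test_null_model_is_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 500) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -20.0, 100)     # fitted below null
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -5.0, 0)

    def test_invariant_to_predictor_rescaling(self, small_cohort):
        res_years = MissingnessModel(small_cohort, ["age"]).fit()
        data = small_cohort.participants.copy()
        decades = small_cohort.subset(data["id"])
        decades.participants["age"] = decades.participants["age"] / 10.0
        res_decades = MissingnessModel(decades, ["age"]).fit()
        assert res_years.nagelkerke_r2 == pytest.approx(
            res_decades.nagelkerke_r2, abs=1e-8)

    def test_completion_variance_explained_band(self, study_cohort):
        res = MissingnessModel(study_cohort, ["completion"]).fit()
        assert 0.45 < res.nagelkerke_r2 < 0.75


class TestAUROC:
    def test_rank_formulation_equals_pairwise_brute_force(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50).round(1)   # force ties
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        pos, neg = scores[labels], scores[~labels]
        brute = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0
            for p in pos for q in neg])
        assert abs(auroc_rank(scores, labels) - brute) < 1e-12

    def test_matches_sklearn_trapezoidal(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        labels[:2] = [True, False]
        assert abs(auroc_rank(scores, labels)
                   - roc_auc_score(labels, scores)) < 1e-12

    def test_no_information_limit(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.36
        assert abs(auroc_rank(scores, labels) - 0.5) < 0.02

    def test_delong_ci_brackets_point(self):
        rng = np.random.default_rng(3)
        labels = rng.random(400) < 0.4
        scores = rng.normal(size=400) + labels
        auc, lo, hi = delong_ci(scores, labels)
        assert lo < auc < hi
        assert 0.02 < hi - lo < 0.2

    def test_completion_model_auroc_band(self, study_cohort):
        res = MissingnessModel(study_cohort, ["completion"]).fit()
        cm = res.classification_metrics()
        assert 0.84 < cm.auroc < 0.92
        assert cm.auroc_ci[0] < cm.auroc < cm.auroc_ci[1]


class TestClassificationMetrics:
    def test_prevalence_rule_nondegenerate_for_weak_predictor(self, study_cohort):
        res = MissingnessModel(study_cohort, ["gender"]).fit()
        cm = res.classification_metrics("prevalence")
        assert not cm.degenerate
        assert 5 < cm.sensitivity < 95
        assert 5 < cm.specificity < 95

    def test_fixed_threshold_degenerates_for_weak_predictor(self, study_cohort):
        res = MissingnessModel(study_cohort, ["gender"]).fit()
        with pytest.warns(UserWarning):
            cm = res.classification_metrics("fixed")
        assert cm.degenerate
        assert cm.sensitivity == 0.0 and cm.specificity == 100.0

    def test_accuracy_consistent_with_confusion(self, small_cohort):
        res = MissingnessModel(small_cohort, ["completion"]).fit()
        cm = res.classification_metrics()
        tp, fn, tn, fp = cm.confusion
        assert cm.accuracy == pytest.approx(100 * (tp + tn) / (tp + fn + tn + fp))


class TestOddsProbability:
    @pytest.mark.parametrize("odds,ref,expected", [
        (162.104, 0.10, 0.9474),
        (106.01, 0.10, 0.9218),
        (1.0, 0.36, 0.36),
        (1.0, 0.05, 0.05),
    ])
    def test_known_conversions(self, odds, ref, expected):
        assert odds_to_probability(odds, ref) == pytest.approx(expected,
                                                               abs=5e-4)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.05, 50), st.floats(0.05, 0.95))
    def test_roundtrip_and_monotonicity(self, odds, ref):
        p = odds_to_probability(odds, ref)
        assert 0 < p < 1
        assert probability_to_odds_ratio(p, ref) == pytest.approx(odds,
                                                                  rel=1e-9)
        assert odds_to_probability(odds * 1.1, ref) > p
        assert odds_to_probability(odds, min(ref * 1.1, 0.96)) >= p - 1e-12

    def test_boundary_errors(self):
        with pytest.raises(ValueError):
            odds_to_probability(0.0, 0.5)
        with pytest.raises(ValueError):
            odds_to_probability(2.0, 0.0)
        with pytest.raises(ValueError):
            odds_to_probability(2.0, 1.0)


class TestRelativeRiskIncrement:
    def test_reference_case_is_zero(self):
        assert relative_risk_increment(0.36, 0.36) == 0.0

    def test_per_point_severity_effect(self):
        """OR 1.037 per point at a 36% average: +2.3% relative risk."""
        p1 = odds_to_probability(1.037, 0.36)
        assert relative_risk_increment(p1, 0.36) == pytest.approx(2.345,
                                                                  abs=0.01)

    def test_unit_odds_ratio_gives_zero_model_rri(self, cohort_factory):
        rng = np.random.default_rng(4)
        records = [{"id": i, "age": float(a),
                    "phq9": (10, 8, None if m else 6)}
                   for i, (a, m) in enumerate(zip(
                       rng.normal(40, 10, 400), rng.random(400) < 0.4))]
        cohort = cohort_factory(records)
        res = MissingnessModel(cohort, ["age"]).fit()
        (risk,) = res.risk_estimates()
        assert abs(risk.rri_pct) < 3.0    # null effect, sampling error only


class TestSelection:
    def test_single_candidate_included_iff_significant(self, study_cohort):
        res = fit_multivariate(study_cohort, ["completion"])
        assert res.selected_predictors == ["completion"]
        with pytest.raises(ValueError):
            # gender has a generating odds ratio of 1: no entry at P=.01
            fit_multivariate(study_cohort, ["gender"])

    def test_forward_and_backward_agree_on_strong_signal(self, study_cohort):
        candidates = ["completion", "phq9_pre", "age", "gender", "employment"]
        rules = fit_multivariate(study_cohort, candidates,
                                 selection_rule="all")
        fwd = set(rules["forward"].selected_predictors)
        bwd = set(rules["backward"].selected_predictors)
        step = set(rules["stepwise"].selected_predictors)
        assert fwd == bwd == step
        assert {"completion", "phq9_pre", "age"} <= fwd
        assert "gender" not in fwd

    def test_empty_candidates_rejected(self, study_cohort):
        with pytest.raises(ValueError):
            fit_multivariate(study_cohort, [])


class TestInteraction:
    def test_additive_truth_gives_nonsignificant_interaction(self, study_cohort):
        """The generator's missingness effects are additive on the logit
        scale, so the completion-by-severity product term should be null."""
        w = missingness_interaction_test(study_cohort, "completion",
                                         "phq9_pre")
        assert w.pvalue > 0.05
        assert not w.flagged

    def test_built_in_interaction_detected(self, cohort_factory):
        """A strata-dependent severity effect (odds ratio doubled in one
        stratum) is picked up by the product-term Wald test."""
        rng = np.random.default_rng(5)
        n = 6000
        gender = rng.random(n) < 0.5
        severity = rng.integers(0, 20, n)
        eta = -1.0 + np.where(gender, np.log(1.10), np.log(1.10 * 2) ) * \
            (severity - 10) / 5.0
        missing = rng.random(n) < 1 / (1 + np.exp(-eta))
        records = [{"id": i, "gender": int(g),
                    "phq9": (int(s), 8, None if m else 6)}
                   for i, (g, s, m) in enumerate(zip(gender, severity, missing))]
        w = missingness_interaction_test(cohort_factory(records), "gender",
                                         "phq9_pre")
        assert w.pvalue < 0.05

    def test_constant_predictor_rejected(self, cohort_factory):
        cohort = cohort_factory([
            {"id": 0, "gender": 1, "phq9": (10, 8, None)},
            {"id": 1, "gender": 1, "phq9": (12, 8, 6)},
        ])
        with pytest.raises(NoContrastError):
            missingness_interaction_test(cohort, "gender", "phq9_pre")


class TestComorbidityCoding:
    def test_both_reference_codings_supported(self, study_cohort):
        plain = MissingnessModel(study_cohort, ["comorbid"]).fit()
        flipped = MissingnessModel(study_cohort, ["comorbid"],
                                   comorbid_reference="comorbid").fit()
        o1 = plain.odds_ratios()["odds_ratio"].iloc[0]
        o2 = flipped.odds_ratios()["odds_ratio"].iloc[0]
        assert o1 == pytest.approx(1 / o2, rel=1e-6)
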