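import numpy as np
import pytest

from misscase import SimConfig, generate_cohort, simulate
from misscase.replacement import (MIConfig, ReplacementAnalysis,
                                  ReplacementEstimate, compare_to_mcar)
from misscase.simulate import expected_change_ratio


@pytest.fixture(scope="module")
def analysis(small_cohort):
    return ReplacementAnalysis(small_cohort, "phq9", seed=3)


def make_estimate(mean, lo, hi):
    return ReplacementEstimate(method="x", mean=mean, ci=(lo, hi),
                               se=(hi - lo) / 3.92, cohort_mean=mean)


class TestCompareToMcar:
    def test_printed_adherence_row_arithmetic(self):
        """8.1 vs 6.3 is +28.6%, printing as 29, and sits above MCAR."""
        mcar = make_estimate(6.3, 6.2, 6.5)
        adj = make_estimate(8.1, 8.1, 8.2)
        pct, verdict = compare_to_mcar(adj, mcar)
        assert round(pct) == 29
        assert verdict == "above"

    def test_printed_bocf_row_arithmetic(self):
        pct, _ = compare_to_mcar(make_estimate(13.1, 12.8, 13.3),
                                 make_estimate(6.3, 6.2, 6.5))
        assert pct == pytest.approx(107.94, abs=0.01)
        assert round(pct) == 108

    def test_identical_estimates_equivalent(self):
        est = make_estimate(6.3, 6.25, 6.35)
        pct, verdict = compare_to_mcar(est, make_estimate(6.3, 6.2, 6.5))
        assert pct == 0.0
        assert verdict == "equivalent"

    def test_verdict_antisymmetry(self):
        mcar = make_estimate(6.3, 6.2, 6.5)
        above = make_estimate(8.0, 7.8, 8.2)
        below = make_estimate(4.6, 4.4, 4.8)
        assert compare_to_mcar(above, mcar)[1] == "above"
        assert compare_to_mcar(below, mcar)[1] == "below"

    def test_partial_overlap_is_inconclusive(self):
        mcar = make_estimate(6.3, 6.2, 6.5)
        straddle = make_estimate(6.4, 5.9, 6.9)
        assert compare_to_mcar(straddle, mcar)[1] == "inconclusive"

    def test_zero_mcar_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compare_to_mcar(make_estimate(5, 4, 6), make_estimate(0, 0, 0))


class TestMcar:
    def test_equals_time_only_marginal_mean(self, analysis):
        """Identity oracle: every missing case receives the fitted marginal
        mean, so the estimate equals it to numerical precision."""
        est = analysis.mcar()
        gee = analysis._fits[()].gee_results
        marginal = float(np.exp(gee.params["Intercept"] + gee.params["time"])) - 1.0
        assert est.mean == pytest.approx(marginal, abs=1e-9)
        assert est.relative_pct == 0.0
        assert est.verdict == "equivalent"

    def test_no_missing_cases(self):
        cohort = generate_cohort(SimConfig(n=300), seed=31)  # no dropout
        ra = ReplacementAnalysis(cohort, "phq9", seed=0)
        est = ra.mcar()
        observed = cohort.scores_wide("phq9")["post"]
        assert est.mean == pytest.approx(observed.mean(), rel=0.05)
        assert est.verdict == "equivalent"
        bocf = ra.bocf()
        assert bocf.mean == pytest.approx(observed.mean(), abs=1e-9)

    def test_no_observed_post_rejected(self, cohort_factory):
        cohort = cohort_factory([
            {"id": i, "phq9": (10, 8, None)} for i in range(10)])
        with pytest.raises(ValueError):
            ReplacementAnalysis(cohort, "phq9")


class TestMar:
    def test_empty_covariates_reduce_to_mcar(self, analysis):
        est = analysis.mar([])
        mcar = analysis.mcar()
        assert est.mean == mcar.mean
        assert est.ci == mcar.ci
        assert est.verdict == "equivalent"

    def test_adherence_adjustment_lands_above_mcar(self, analysis):
        est = analysis.mar(["completion"])
        assert est.verdict == "above"
        assert 15 < est.relative_pct < 45

    def test_outcome_null_covariate_is_equivalent(self, analysis):
        est = analysis.mar(["gender"])
        assert est.verdict == "equivalent"
        assert abs(est.relative_pct) < 2.0

    def test_extrapolation_flagged(self, cohort_factory):
        records = [{"id": i, "modules_completed": 5, "phq9": (10, 8, 6)}
                   for i in range(30)]
        records += [{"id": 30 + i, "modules_completed": 1,
                     "phq9": (14, 13, None)} for i in range(10)]
        cohort = cohort_factory(records)
        ra = ReplacementAnalysis(cohort, "phq9", seed=0)
        with pytest.warns(UserWarning, match="extrapolat"):
            est = ra.mar(["completion"])
        assert est.extrapolated


class TestCarriedForward:
    def test_locf_uses_mid_then_pre(self, cohort_factory):
        completers = [{"id": 2 + i, "phq9": (8 + i % 6, 6 + i % 6, 4 + i % 5)}
                      for i in range(20)]
        cohort = cohort_factory([
            {"id": 0, "phq9": (20, 14, None)},       # mid observed -> 14
            {"id": 1, "phq9": (20, None, None)},     # no mid -> 20 (= BOCF)
        ] + completers)
        ra = ReplacementAnalysis(cohort, "phq9", seed=0)
        locf = ra.locf()
        assert locf.mean == pytest.approx((14 + 20) / 2)
        bocf = ra.bocf()
        assert bocf.mean == pytest.approx(20.0)

    def test_bocf_identity_oracle(self, analysis, small_cohort):
        est = analysis.bocf()
        wide = small_cohort.scores_wide("phq9")
        baseline_missing = wide["pre"][wide["post"].isna()].mean()
        assert est.mean == pytest.approx(baseline_missing, abs=1e-12)

    def test_carried_forward_ordering(self, analysis):
        """LOCF sits between the adherence-adjusted estimate and BOCF."""
        mar = analysis.mar(["completion", "phq9_pre"])
        locf = analysis.locf()
        bocf = analysis.bocf()
        assert mar.mean < locf.mean < bocf.mean


class TestMultipleImputation:
    def test_intercept_only_reduces_to_mcar(self, analysis):
        est = analysis.mi(MIConfig(m=40, covariates=(), use_pre=False,
                                   use_mid=False, seed=5))
        mcar = analysis.mcar()
        assert est.mean == pytest.approx(mcar.mean, abs=0.5)

    def test_pooling_stability_in_m(self, analysis):
        e2 = analysis.mi(MIConfig(m=2, covariates=("completion",), seed=6))
        e50 = analysis.mi(MIConfig(m=50, covariates=("completion",), seed=6))
        between_sd = np.sqrt(e50.mi_between)
        assert abs(e2.mean - e50.mean) < max(2 * between_sd, 0.2)

    def test_adjusted_mi_above_mcar(self, analysis):
        est = analysis.mi(MIConfig(m=20, covariates=("completion", "phq9_pre"),
                                   seed=7))
        assert est.verdict == "above"
        mar = analysis.mar(["completion", "phq9_pre"])
        assert abs(est.mean - mar.mean) < 1.5

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            MIConfig(m=1)


class TestMixedModel:
    def test_zero_random_variance_predicts_fixed_curve(self, cohort_factory):
        records = [{"id": i, "phq9": (16, 12, 8 if i % 3 else None)}
                   for i in range(45)]
        cohort = cohort_factory(records)
        ra = ReplacementAnalysis(cohort, "phq9", seed=0)
        est = ra.mlm(covariates=())
        # every subject shares one deterministic trajectory 16 -> 12 -> 8-ish
        assert est.mean == pytest.approx(8.0, abs=0.6)

    def test_noise_free_predictions_match_generator(self):
        cfg = SimConfig(n=400, noise=False, integer_scores=False)
        cohort = simulate(cfg, seed=33)
        ra = ReplacementAnalysis(cohort, "phq9", seed=0)
        est = ra.mlm(("completion",))
        wide = cohort.scores_wide("phq9")
        miss = wide["post"].isna()
        ratio = expected_change_ratio(cohort, cfg, "phq9")
        truth = ((wide["pre"][miss] + 1) * ratio[miss] - 1).mean()
        assert est.mean == pytest.approx(truth, abs=0.2)

    def test_adherence_mlm_above_mcar(self, analysis):
        est = analysis.mlm(("completion",))
        assert est.verdict == "above"


class TestOrderingAndTable:
    def test_replacement_ordering_single_seed(self, analysis):
        """Mean replacement scores reproduce the expected ordering:
        MCAR < MAR(baseline) < MAR(completion) < MAR(completion+baseline)
        <= LOCF < BOCF."""
        means = [
            analysis.mcar().mean,
            analysis.mar(["phq9_pre"]).mean,
            analysis.mar(["completion"]).mean,
            analysis.mar(["completion", "phq9_pre"]).mean,
            analysis.locf().mean,
            analysis.bocf().mean,
        ]
        assert all(a < b + 1e-9 for a, b in zip(means, means[1:]))

    def test_full_table_structure(self, small_cohort):
        ra = ReplacementAnalysis(small_cohort, "gad7", seed=4)
        table = ra.table(MIConfig(m=5, covariates=("completion", "gad7_pre"),
                                  seed=4))
        assert table["method"].str.contains("MCAR").any()
        assert table["method"].str.contains("LOCF").any()
        assert (table["ci_lower"] <= table["ci_upper"]).all()
        # first row: pretreatment scores of the missing subset
        wide = small_cohort.scores_wide("gad7")
        pre_missing = wide["pre"][wide["post"].isna()].mean()
        assert table.iloc[0]["mean"] == pytest.approx(pre_missing, abs=1e-9)

    def test_seeded_reproducibility(self, small_cohort):
        a = ReplacementAnalysis(small_cohort, "phq9", seed=11).mi(
            MIConfig(m=5, seed=11))
        b = ReplacementAnalysis(small_cohort, "phq9", seed=11).mi(
            MIConfig(m=5, seed=11))
        assert a.mean == b.mean
        assert a.ci == b.ci
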