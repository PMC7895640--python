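import numpy as np
import pandas as pd
import pytest

from misscase import Cohort, SimConfig, generate_cohort, simulate
from misscase.config import ConfigError
from misscase.simulate import (apply_dropout, expected_change_ratio,
                               missingness_probability, simulate_trajectories)


def flat_config(**kw):
    """Config with all moderation and dropout heterogeneity switched off."""
    base = dict(
        completion_odds_ratios={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
        severity_or_per_point=1.0, age_or_per_year=1.0,
        completion_change_multipliers={
            s: {k: 1.0 for k in range(1, 6)} for s in ("phq9", "gad7", "k10")},
        severity_change_multipliers={"phq9": 1.0, "gad7": 1.0, "k10": 1.0},
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateCohort:
    def test_completion_counts_match_proportions(self):
        cohort = generate_cohort(SimConfig(), seed=11)
        counts = cohort.participants["modules_completed"].value_counts()
        expected = {1: 513, 2: 715, 3: 718, 4: 653, 5: 4102}
        for level, exp in expected.items():
            p = exp / 6701
            sd = np.sqrt(6701 * p * (1 - p))
            assert abs(counts[level] - exp) < 4 * sd

    def test_minimal_cohort_of_one(self):
        cohort = generate_cohort(SimConfig(n=1), seed=0)
        assert cohort.n == 1
        per_scale = cohort.measurements.groupby("scale")["timepoint"].nunique()
        assert (per_scale >= 2).all()

    def test_zero_interscale_correlation(self):
        cfg = SimConfig(n=10_000, interscale_correlation=0.0)
        cohort = generate_cohort(cfg, seed=3)
        r = cohort.baseline("phq9").corr(cohort.baseline("gad7"))
        assert abs(r) < 0.03

    def test_configured_interscale_correlation_recovered(self):
        cohort = generate_cohort(SimConfig(n=10_000), seed=3)
        r = cohort.baseline("phq9").corr(cohort.baseline("gad7"))
        assert abs(r - 0.6) < 0.05

    def test_reproducible_from_seed(self):
        a = simulate(SimConfig(n=400), seed=5)
        b = simulate(SimConfig(n=400), seed=5)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(completion_proportions=(0.3, 0.3, 0.2, 0.1, 0.05))
        with pytest.raises(ConfigError):
            SimConfig(within_subject_correlation=1.2)
        with pytest.raises(ConfigError):
            SimConfig(reference_missing_prob=0.0)
        with pytest.raises(ConfigError):
            SimConfig(time_coefficients={"phq9": 1.4, "gad7": 0.5, "k10": 0.5})
        with pytest.raises(ConfigError):
            SimConfig(n=0)


class TestTrajectories:
    def test_noise_free_multiplicative_identity(self):
        """Without noise the shifted post/pre ratio equals the configured
        product of multipliers exactly (before rounding)."""
        cfg = SimConfig(n=300, noise=False, integer_scores=False)
        cohort = generate_cohort(cfg, seed=2)
        for scale, off in (("phq9", 0), ("k10", 10)):
            wide = cohort.scores_wide(scale)
            ratio = expected_change_ratio(cohort, cfg, scale)
            got = (wide["post"].values - off + 1) / (wide["pre"].values - off + 1)
            want = ratio.values
            free = (wide["post"].values - off) > 1e-9  # rows not floor-clipped
            assert np.allclose(got[free], want[free], atol=1e-10)

    def test_no_change_limit(self):
        cfg = flat_config(n=200, noise=False,
                          time_coefficients={"phq9": 1.0, "gad7": 1.0,
                                             "k10": 1.0})
        cohort = generate_cohort(cfg, seed=4)
        for scale in ("phq9", "gad7", "k10"):
            wide = cohort.scores_wide(scale)
            assert (wide["post"] == wide["pre"]).all()
            assert (wide["mid"] == wide["pre"]).all()

    def test_noise_free_rounding_rule(self):
        cfg = flat_config(n=500, noise=False,
                          time_coefficients={"phq9": 0.519, "gad7": 0.519,
                                             "k10": 0.63})
        cohort = generate_cohort(cfg, seed=6)
        wide = cohort.scores_wide("phq9")
        expected = np.clip(np.round((wide["pre"] + 1) * 0.519 - 1), 0, 27)
        assert (wide["post"] == expected).all()

    def test_completion_multiplier_forces_ratio(self):
        """Reference ratio 0.5 with a 1.4 multiplier for minimal completers
        gives ratio 0.7: pre=20 -> post=14."""
        mult = {s: {1: 1.4, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0}
                for s in ("phq9", "gad7", "k10")}
        cfg = flat_config(n=1000, noise=False,
                          completion_change_multipliers=mult,
                          time_coefficients={"phq9": 0.5, "gad7": 0.5,
                                             "k10": 0.5})
        cohort = generate_cohort(cfg, seed=8)
        d = cohort.design_frame().set_index("id")
        wide = cohort.scores_wide("phq9")
        ones = d.index[(d["modules_completed"] == 1)]
        sel = wide.loc[ones]
        sel = sel[sel["pre"] == 20]
        assert len(sel) > 0
        assert (sel["post"] == 14).all()     # round(21*0.7 - 1)

    def test_mid_is_geometric_midpoint(self):
        cfg = flat_config(n=300, noise=False, integer_scores=False,
                          time_coefficients={"phq9": 0.49, "gad7": 0.49,
                                             "k10": 0.49})
        cohort = generate_cohort(cfg, seed=9)
        wide = cohort.scores_wide("phq9")
        free = wide["mid"] > 1e-9            # rows not floor-clipped
        got = (wide["mid"][free] + 1) / (wide["pre"][free] + 1)
        assert np.allclose(got, 0.7, atol=1e-9)  # sqrt(0.49)

    def test_within_subject_correlation_target(self, study_cohort):
        wide = study_cohort.scores_wide("phq9")
        assert abs(wide["pre"].corr(wide["mid"]) - 0.72) < 0.05


class TestDropout:
    def test_homogeneous_mcar_limit(self):
        cfg = flat_config(n=20_000, reference_missing_prob=0.36)
        cohort = simulate(cfg, seed=10)
        d = cohort.design_frame()
        by_level = d.groupby("modules_completed")["missing"].mean()
        assert np.allclose(by_level, 0.36, atol=0.03)
        assert abs(d["missing"].mean() - 0.36) < 0.01

    @pytest.mark.parametrize("level,odds,expected_pct", [
        (1, 162.104, 94.7),   # q*OR/(1+q*OR) at q=1/9
        (2, 106.01, 92.2),
    ])
    def test_completion_odds_drive_missingness(self, level, odds, expected_pct):
        cfg = SimConfig(n=100_000, reference_missing_prob=0.10,
                        severity_or_per_point=1.0, age_or_per_year=1.0)
        cohort = simulate(cfg, seed=12)
        d = cohort.design_frame()
        got = 100 * d.loc[d["modules_completed"] == level, "missing"].mean()
        assert abs(got - expected_pct) < 1.0

    def test_probability_model_matches_formula(self):
        cfg = SimConfig(n=50)
        cohort = generate_cohort(cfg, seed=13)
        p = missingness_probability(cohort, cfg)
        assert ((p > 0) & (p < 1)).all()
        d = cohort.design_frame().set_index("id")
        full = p[d["modules_completed"] == 5]
        ones = p[d["modules_completed"] == 1]
        if len(full) and len(ones):
            assert ones.min() > full.max()

    def test_pre_and_mid_never_deleted(self, study_cohort):
        m = study_cohort.measurements
        for tp in ("pre", "mid"):
            per = m[m["timepoint"] == tp].groupby("id")["scale"].nunique()
            assert len(per) == study_cohort.n
            assert (per == 3).all()

    def test_dropout_joint_across_scales(self, study_cohort):
        post = study_cohort.measurements.query("timepoint == 'post'")
        nsc = post.groupby("id")["scale"].nunique()
        assert set(nsc.unique()) == {3}

    def test_overall_missingness_near_study_rate(self, study_cohort):
        assert abs(study_cohort.missing_post.mean() - 0.3626) < 0.025


class TestCohortIO:
    def test_csv_roundtrip(self, tmp_path):
        cohort = simulate(SimConfig(n=120), seed=14)
        cohort.to_csv(tmp_path)
        back = Cohort.from_csv(tmp_path)
        pd.testing.assert_frame_equal(
            cohort.participants.reset_index(drop=True),
            back.participants.reset_index(drop=True), check_dtype=False)
        assert len(back.measurements) == len(cohort.measurements)
        assert back.missing_post.sum() == cohort.missing_post.sum()

    def test_sim_config_json_roundtrip(self, tmp_path):
        cfg = SimConfig(n=42, interscale_correlation=0.3,
                        completion_odds_ratios={1: 10.0, 2: 5.0, 3: 2.0,
                                                4: 1.5})
        cfg.to_json(tmp_path / "sim.json")
        back = SimConfig.from_json(tmp_path / "sim.json")
        assert back == cfg

    def test_comorbidity_definition(self, cohort_factory):
        cohort = cohort_factory([
            {"id": 0, "phq9": (12, 9, 7), "gad7": (9, 7, 5)},   # both above
            {"id": 1, "phq9": (9, 7, 5), "gad7": (9, 7, 5)},    # phq below
            {"id": 2, "phq9": (12, 9, 7), "gad7": (7, 5, 4)},   # gad below
        ])
        assert cohort.comorbid.tolist() == [1, 0, 0]
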