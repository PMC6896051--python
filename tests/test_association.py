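import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grspipe.association import (
    GATED_VARIABLES,
    ModelSpec,
    build_model_frame,
    classify_glycemic_status,
    fit_linear,
    fit_logistic,
    run_association_suite,
    shapiro_wilk_gate,
    two_sample_t,
    two_step_transform,
)
from grspipe.effect_weights import WeightSet, derive_weights
from grspipe.risk_scores import score_cohorts

from conftest import make_cohort


class TestGlycemicClassification:
    @pytest.mark.parametrize(
        "fg,treated,category,binary",
        [
            (5.0, False, "normal", False),
            (5.6, False, "prediabetes", True),   # inclusive lower bound
            (6.0, False, "prediabetes", True),
            (6.9, False, "prediabetes", True),
            (7.0, False, "t2dm", True),
            (4.9, True, "t2dm", True),           # treatment overrides FG
        ],
    )
    def test_thresholds(self, fg, treated, category, binary):
        status = classify_glycemic_status(fg, treated)
        assert status.category == category
        assert status.binary_outcome is binary

    def test_strict_lower_bound_flag(self):
        assert classify_glycemic_status(5.6, False, inclusive_lower=False).category == "normal"

    def test_nonpositive_fg_rejected(self):
        with pytest.raises(ValueError):
            classify_glycemic_status(0.0, False)


class TestTwoStepTransform:
    def test_preserves_mean_and_sd(self):
        x = np.array([1.0, 2.0, 100.0])
        y = two_step_transform(x)
        assert y.mean() == pytest.approx(x.mean(), abs=1e-9)
        assert y.std(ddof=1) == pytest.approx(x.std(ddof=1), abs=1e-9)
        assert np.all(np.diff(y) > 0)  # monotone in the original order

    def test_rank_preservation_on_random_input(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, 500)
        y = two_step_transform(x)
        assert stats.spearmanr(x, y).statistic == pytest.approx(1.0)

    def test_normalises_lognormal_samples(self):
        """After the transform, Shapiro-Wilk should stop rejecting in about
        95% of draws (its nominal false-positive rate)."""
        passes = 0
        reps = 100
        for seed in range(reps):
            x = np.random.default_rng(seed).lognormal(0, 1, 1000)
            if stats.shapiro(two_step_transform(x)).pvalue >= 0.05:
                passes += 1
        assert passes / reps >= 0.90

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_step_transform(np.ones(10))


class TestShapiroGate:
    def test_calibration_on_normal_samples(self):
        flags = sum(
            shapiro_wilk_gate(np.random.default_rng(seed).normal(0, 1, 500))
            for seed in range(100)
        )
        assert flags / 100 < 0.15  # nominal 5% false-trigger rate

    def test_detects_exponential_skew(self):
        x = np.random.default_rng(0).exponential(1, 500)
        assert shapiro_wilk_gate(x)

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate(np.ones(10))
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])


class TestTwoSampleT:
    def test_identical_groups_are_null(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.674, abs=1e-3)
        assert res["p"] == pytest.approx(0.0213, abs=1e-3)
        assert res["df"] == 4

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])

    def test_detects_study_scale_score_gap(self, small_panel):
        """A true GRS gap of ~0.6 alleles at n = 1394/1008 is essentially
        always significant at p < 0.001."""
        from grspipe.risk_scores import score_cohort

        ws = WeightSet(panel=small_panel, weights=np.ones(3))
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, [0.6, 0.5, 0.5], (1394, 3))
            b = rng.binomial(2, [0.4, 0.4, 0.4], (1008, 3))
            sa = score_cohort(make_cohort(a, small_panel, label="A"), ws)
            sb = score_cohort(make_cohort(b, small_panel, label="B"), ws)
            res = two_sample_t(sa.scores["grs"], sb.scores["grs"])
            detected += res["p"] < 0.001
        assert detected == 5


def _regression_frame(n=400, seed=0, beta_score=0.4, logistic=False):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "grs": rng.binomial(32, 0.5, n).astype(float),
            "wgrs": rng.normal(1.4, 0.3, n),
            "female": rng.integers(0, 2, n).astype(float),
            "age": rng.normal(45, 12, n),
            "bmi": rng.normal(27, 5, n),
            "hdl": rng.lognormal(0.3, 0.3, n),
            "tg": rng.lognormal(0.3, 0.6, n),
            "roma": rng.integers(0, 2, n).astype(float),
        }
    )
    eta = -2.0 + beta_score * (frame["wgrs"] - 1.4)
    if logistic:
        frame["t2dm_status"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    frame["fasting_glucose"] = 4.8 + beta_score * frame["wgrs"] + rng.normal(0, 0.5, n)
    return frame


class TestLinearModel:
    def test_noiseless_recovery_is_exact(self):
        n = 50
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "grs": x,
                "fasting_glucose": 2.0 * x + 1.0,
            }
        )
        spec = ModelSpec("fasting_glucose", "grs", covariates=(), transform=False)
        res = fit_linear(spec, frame)
        assert res.coefficient("grs")["estimate"] == pytest.approx(2.0, abs=1e-10)

    def test_row_permutation_invariance(self):
        frame = _regression_frame(seed=5)
        spec = ModelSpec("fasting_glucose", "wgrs", transform=False)
        a = fit_linear(spec, frame)
        b = fit_linear(spec, frame.sample(frac=1, random_state=0))
        assert a.coefficient("wgrs")["estimate"] == pytest.approx(
            b.coefficient("wgrs")["estimate"]
        )

    def test_residuals_orthogonal_to_design(self):
        frame = _regression_frame(seed=7)
        spec = ModelSpec("fasting_glucose", "wgrs", transform=False)
        res = fit_linear(spec, frame)
        import statsmodels.api as sm

        X = sm.add_constant(frame[list(spec.predictors)].astype(float))
        beta = res.table.set_index("term")["estimate"]
        fitted = X.to_numpy() @ beta[X.columns].to_numpy()
        resid = frame["fasting_glucose"].to_numpy() - fitted
        assert np.abs(X.to_numpy().T @ resid).max() < 1e-6

    def test_collinear_design_rejected(self):
        frame = _regression_frame(seed=2)
        frame["tg"] = 2 * frame["hdl"]  # exact collinearity
        spec = ModelSpec("fasting_glucose", "grs", transform=False,
                         covariates=("hdl", "tg"))
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(spec, frame)


class TestLogisticModel:
    def test_reproduces_2x2_cross_product_odds_ratio(self):
        # exposed cases/controls 30/70, unexposed 15/85
        frame = pd.DataFrame(
            {
                "grs": [1.0] * 100 + [0.0] * 100,
                "t2dm_status": [1] * 30 + [0] * 70 + [1] * 15 + [0] * 85,
            }
        )
        spec = ModelSpec("t2dm_status", "grs", covariates=(), transform=False)
        res = fit_logistic(spec, frame)
        expected = (30 * 85) / (70 * 15)
        assert res.coefficient("grs")["estimate"] == pytest.approx(
            expected, rel=1e-6
        )

    def test_cross_product_identity_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(5, 80, 4)
            frame = pd.DataFrame(
                {
                    "grs": [1.0] * (a + b) + [0.0] * (c + d),
                    "t2dm_status": [1] * a + [0] * b + [1] * c + [0] * d,
                }
            )
            spec = ModelSpec("t2dm_status", "grs", covariates=(), transform=False)
            res = fit_logistic(spec, frame)
            assert res.coefficient("grs")["estimate"] == pytest.approx(
                (a * d) / (b * c), rel=1e-6
            )

    def test_one_class_outcome_rejected(self):
        frame = _regression_frame(seed=3, logistic=True)
        frame["t2dm_status"] = 0
        spec = ModelSpec("t2dm_status", "wgrs", transform=False)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(spec, frame)

    def test_complete_separation_rejected(self):
        frame = pd.DataFrame(
            {
                "grs": np.r_[np.zeros(20), np.ones(20)],
                "t2dm_status": np.r_[np.zeros(20), np.ones(20)].astype(int),
            }
        )
        spec = ModelSpec("t2dm_status", "grs", covariates=(), transform=False)
        with pytest.raises((ValueError, Exception)):
            fit_logistic(spec, frame)

    def test_type_i_error_calibrates_under_the_null(self):
        """With no true effect, the score term should reject at ~5%."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            frame = _regression_frame(n=300, seed=seed, beta_score=0.0,
                                      logistic=True)
            spec = ModelSpec("t2dm_status", "wgrs", covariates=(),
                             transform=False)
            res = fit_logistic(spec, frame)
            rejections += res.coefficient("wgrs")["p"] < 0.05
        rate = rejections / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se


@pytest.fixture(scope="module")
def two_cohorts(panel):
    from grspipe.synthetic_cohort import generate_two_populations, load_preset
    from grspipe.cohort_io import complete_case_filter
    from dataclasses import replace

    cfg_g = replace(load_preset("general_like"), n=500)
    cfg_r = replace(load_preset("roma_like"), n=400)
    g, r = generate_two_populations(cfg_g, cfg_r, seed=99, panel=panel)
    return complete_case_filter(g), complete_case_filter(r)


class TestAssociationSuite:
    def test_grid_contains_twelve_models(self, two_cohorts, panel):
        g, r = two_cohorts
        scores = score_cohorts([g, r], derive_weights(panel))
        results = run_association_suite(g, r, scores)
        assert len(results) == 12
        kinds = {(res.spec.score, res.spec.outcome, res.cohort) for res in results}
        assert len(kinds) == 12

    def test_ethnicity_term_only_in_combined_models(self, two_cohorts, panel):
        g, r = two_cohorts
        scores = score_cohorts([g, r], derive_weights(panel))
        for res in run_association_suite(g, r, scores):
            terms = set(res.table["term"])
            if res.cohort == "combined":
                assert "roma" in terms
            else:
                assert "roma" not in terms

    def test_or_cis_bracket_their_estimates(self, two_cohorts, panel):
        g, r = two_cohorts
        scores = score_cohorts([g, r], derive_weights(panel))
        for res in run_association_suite(g, r, scores):
            t = res.table
            assert (t["ci_low"] <= t["estimate"] + 1e-12).all()
            assert (t["estimate"] <= t["ci_high"] + 1e-12).all()

    def test_no_genetic_difference_null_leaves_score_or_near_one(self, panel):
        """Two populations with identical allele frequencies but an
        environmental fasting-glucose shift: the ethnicity term carries the
        signal, the score terms stay null."""
        from dataclasses import replace
        from grspipe.cohort_io import complete_case_filter
        from grspipe.synthetic_cohort import generate_two_populations, load_preset

        cfg_g = replace(load_preset("general_like"), n=2000, beta_scale=0.0,
                        missing_genotype_rate=0.0, missing_phenotype_rate=0.0)
        cfg_r = replace(
            load_preset("roma_like"), n=2000, beta_scale=0.0,
            frequencies=cfg_g.frequencies,
            missing_genotype_rate=0.0, missing_phenotype_rate=0.0,
        )
        g, r = generate_two_populations(cfg_g, cfg_r, seed=13, panel=panel)
        scores = score_cohorts([g, r], derive_weights(panel))
        frame = build_model_frame([g, r], scores)
        spec = ModelSpec("t2dm_status", "grs", include_ethnicity=True,
                         transform=False)
        res = fit_logistic(spec, frame)
        score_row = res.coefficient("grs")
        ethnicity_row = res.coefficient("roma")
        assert score_row["ci_low"] < 1.0 < score_row["ci_high"]
        assert ethnicity_row["estimate"] > 1.5

    def test_exchangeable_cohorts_show_no_score_difference(self, panel):
        from dataclasses import replace
        from grspipe.synthetic_cohort import generate_cohort, load_preset
        from grspipe.risk_scores import score_cohort

        cfg = replace(load_preset("general_like"), n=800,
                      missing_genotype_rate=0.0, missing_phenotype_rate=0.0)
        ws = derive_weights(panel)
        significant = 0
        for seed in range(10):
            a = generate_cohort(cfg, panel, seed=seed * 2 + 1)
            b = generate_cohort(cfg, panel, seed=seed * 2 + 2)
            pa = score_cohort(a, ws).scores["grs"]
            pb = score_cohort(b, ws).scores["grs"]
            significant += two_sample_t(pa, pb)["p"] < 0.05
        assert significant <= 3  # ~5% expected; generous binomial headroom
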