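import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairsig.errors import ValidationError
from pairsig.evaluation import (
    ROCCurve,
    assign_groups,
    association_tests,
    compare_groups_survival,
    encode_covariate,
    independence_analysis,
    optimal_cutoff,
    time_dependent_roc,
)
from pairsig.stattests import rank_sum_test, significance_stars


def clinical_frame(time, event, **extra):
    n = len(time)
    df = pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(n)], "time": time, "event": event}
    )
    for k, v in extra.items():
        df[k] = v
    return df


def scores_series(values):
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))])


class TestTimeDependentROC:
    def test_perfect_separation(self):
        # all cases (t<=5) score above all controls, no censoring
        time = [1, 2, 3, 10, 11, 12]
        event = [1, 1, 1, 1, 1, 1]
        s = scores_series([10, 9, 8, 1, 2, 3])
        roc = time_dependent_roc(s, clinical_frame(time, event), t=5)
        assert roc.auc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_uncensored_mann_whitney_reduction(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        time = rng.exponential(size=n) * 100 + 1
        s = scores_series(rng.standard_normal(n))
        t = float(np.median(time))
        roc = time_dependent_roc(s, clinical_frame(time, np.ones(n, int)), t=t)
        cases = s.to_numpy()[time <= t]
        controls = s.to_numpy()[time > t]
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(cases) * len(controls)), abs=1e-12)

    def test_endpoints_present(self):
        rng = np.random.default_rng(1)
        n = 40
        time = rng.exponential(size=n) * 100 + 1
        event = rng.integers(0, 2, n)
        event[:5] = 1
        roc = time_dependent_roc(
            scores_series(rng.standard_normal(n)),
            clinical_frame(time, event),
            t=float(np.median(time)),
        )
        assert roc.sensitivity[0] == 0 and 1 - roc.specificity[0] == 0
        assert roc.sensitivity[-1] == 1 and roc.specificity[-1] == 0
        assert np.all(np.diff(roc.sensitivity) >= 0)  # non-increasing in threshold

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(2)
        n = 50
        time = rng.exponential(size=n) * 100 + 1
        event = rng.integers(0, 2, n)
        event[:5] = 1
        s = rng.standard_normal(n)
        clin = clinical_frame(time, event)
        a1 = time_dependent_roc(scores_series(s), clin, t=80.0).auc
        a2 = time_dependent_roc(scores_series(np.exp(s)), clin, t=80.0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_horizon_before_first_event(self):
        with pytest.raises(ValidationError, match="precedes"):
            time_dependent_roc(
                scores_series([1.0, 2.0, 3.0]),
                clinical_frame([10, 20, 30], [1, 1, 1]),
                t=5,
            )

    def test_nobody_at_risk_after_horizon(self):
        with pytest.raises(ValidationError):
            time_dependent_roc(
                scores_series([1.0, 2.0, 3.0]),
                clinical_frame([1, 2, 3], [1, 1, 1]),
                t=10,
            )


class TestOptimalCutoff:
    def _roc(self, thresholds, sens, spec):
        return ROCCurve(
            horizon=365.0,
            thresholds=np.asarray(thresholds, float),
            sensitivity=np.asarray(sens, float),
            specificity=np.asarray(spec, float),
            auc=0.5,
        )

    def test_three_point_hand_example(self):
        roc = self._roc([2.0, 1.0, 0.0], [0.4, 0.9, 1.0], [0.95, 0.8, 0.0])
        cut = optimal_cutoff(roc)
        assert cut.cutoff == 1.0
        assert cut.youden == pytest.approx(0.7)

    def test_perfect_curve(self):
        roc = self._roc([2.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0])
        assert optimal_cutoff(roc).youden == pytest.approx(1.0)

    def test_tie_broken_toward_higher_sensitivity(self):
        roc = self._roc([2.0, 1.0], [0.5, 0.8], [0.9, 0.6])  # youden 0.4 both
        cut = optimal_cutoff(roc)
        assert cut.cutoff == 1.0
        assert cut.sensitivity == pytest.approx(0.8)

    def test_aic_reported_with_raw_inputs(self):
        rng = np.random.default_rng(3)
        n = 60
        s = rng.standard_normal(n)
        time = np.exp(-s) * rng.exponential(size=n) * 100 + 1
        roc = time_dependent_roc(
            scores_series(s), clinical_frame(time, np.ones(n, int)),
            t=float(np.median(time)),
        )
        cut = optimal_cutoff(roc)
        assert cut.aic is not None and np.isfinite(cut.aic)


class TestGroups:
    def test_strict_rule_at_cutoff(self):
        g = assign_groups(scores_series([1.0, 2.0, 3.0]), cutoff=2.0)
        assert list(g) == ["low", "low", "high"]

    def test_all_below(self):
        g = assign_groups(scores_series([0.1, 0.2]), cutoff=5.0)
        assert set(g) == {"low"}

    def test_partition_sums(self):
        rng = np.random.default_rng(4)
        s = scores_series(rng.standard_normal(30))
        g = assign_groups(s, cutoff=0.0)
        assert (g == "high").sum() + (g == "low").sum() == 30

    def test_identical_survival_groups(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 1, 1, 1, 1]
        clin = clinical_frame(time, event)
        groups = pd.Series(
            ["high"] * 3 + ["low"] * 3, index=[f"S{i}" for i in range(6)]
        )
        _, chi2, p = compare_groups_survival(groups, clin)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_error(self):
        clin = clinical_frame([1, 2, 3], [1, 1, 1])
        groups = pd.Series(["low"] * 3, index=[f"S{i}" for i in range(3)])
        with pytest.raises(ValidationError):
            compare_groups_survival(groups, clin)

    def test_separated_groups_low_p(self, small_cohort):
        expr, clinical, truth = small_cohort
        lp = pd.Series(truth.linear_predictor)
        groups = assign_groups(lp, cutoff=float(lp.median()))
        _, _, p = compare_groups_survival(groups, clinical)
        assert p < 1e-3


class TestIndependence:
    def test_shapes_and_coding(self, small_cohort):
        _, clinical, truth = small_cohort
        scores = pd.Series(truth.linear_predictor)
        uni, multi = independence_analysis(scores, clinical)
        assert set(uni["covariate"]) == {
            "risk_score", "age", "sex", "stage", "T", "N", "M",
        }
        assert len(multi) == 7  # one HR per covariate
        assert (multi["hr"] > 0).all()

    def test_score_prognostic_covariates_null(self, small_cohort):
        _, clinical, truth = small_cohort
        scores = pd.Series(truth.linear_predictor)
        uni, _ = independence_analysis(scores, clinical)
        row = uni[uni["covariate"] == "risk_score"].iloc[0]
        assert row["p"] < 1e-4
        assert row["hr"] > 1

    def test_duplicated_score_warns_collinear(self, small_cohort, caplog):
        _, clinical, truth = small_cohort
        scores = pd.Series(truth.linear_predictor)
        clin = clinical.copy()
        clin["score_copy"] = scores.loc[clin["sample_id"]].to_numpy()
        with caplog.at_level("WARNING"):
            independence_analysis(scores, clin, covariates=("age", "score_copy"))
        assert "collinear" in caplog.text

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(6)
        n, reps, covered = 80, 200, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            t = rng.exponential(size=n) + 0.01
            from pairsig.survival import fit_cox

            fit = fit_cox(x, t, np.ones(n, int))
            lo, hi = fit.ci95[0]
            covered += lo <= 1.0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_encode_covariate(self):
        assert list(encode_covariate(pd.Series(["I", "IV", "II"]))) == [1, 4, 2]
        assert list(encode_covariate(pd.Series(["T1", "T3"]))) == [1, 3]
        assert list(encode_covariate(pd.Series(["N0", "N2"]))) == [0, 2]
        assert list(encode_covariate(pd.Series([50, 60.0]))) == [50.0, 60.0]
        assert list(encode_covariate(pd.Series(["female", "male"]))) == [0.0, 1.0]


class TestAssociations:
    def test_hand_chi_square(self):
        # 2x2 table [[10,20],[20,10]]: expected all 15, chi2 = 20/3
        n = 60
        groups = pd.Series(
            ["high"] * 30 + ["low"] * 30, index=[f"S{i}" for i in range(n)]
        )
        cat = ["a"] * 10 + ["b"] * 20 + ["a"] * 20 + ["b"] * 10
        clin = clinical_frame(np.ones(n), np.ones(n, int), sex=cat)
        scores = scores_series(np.arange(n, dtype=float))
        out = association_tests(groups, scores, clin, covariates=("sex",))
        chi_row = out[out["test"] == "chi2"].iloc[0]
        assert chi_row["statistic"] == pytest.approx(20 / 3, abs=1e-9)
        assert chi_row["p"] == pytest.approx(0.009823, abs=1e-4)
        assert chi_row["stars"] == "**"
        assert not chi_row["low_expected"]

    def test_identical_distributions_no_star(self):
        n = 40
        groups = pd.Series(
            ["high", "low"] * 20, index=[f"S{i}" for i in range(n)]
        )
        cat = ["a", "a", "b", "b"] * 10
        clin = clinical_frame(np.ones(n), np.ones(n, int), stage=cat)
        out = association_tests(
            groups, scores_series(np.zeros(n)), clin, covariates=("stage",)
        )
        chi_row = out[out["test"] == "chi2"].iloc[0]
        assert chi_row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert chi_row["stars"] == ""

    def test_exact_rank_sum_extreme(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""
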