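import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tempotrain import (
    DataError,
    GeneratingParams,
    auxiliary_tests,
    change_regression,
    cohort_frame,
    fit_lmm,
    listener_threshold_summary,
    paired_change_test,
    run_recovery,
    run_study,
    sample_cohort,
)
from tempotrain.stats import between_within_df, prepost_table


def _azbio(changes, pre=55.0):
    rows = []
    for i, ch in enumerate(changes):
        rows.append((f"L{i}", "pre", pre))
        rows.append((f"L{i}", "post", pre + ch))
    return pd.DataFrame(rows, columns=["listener", "phase", "score"])


class TestPairedChange:
    def test_hand_computed_example(self):
        res = paired_change_test(_azbio([1.0, 2.0, 3.0]))
        assert res.mean_change == pytest.approx(2.0)
        assert res.se == pytest.approx(1 / np.sqrt(3))
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_no_change_gives_null_statistic(self):
        res = paired_change_test(_azbio([0.0, 0.0, 0.0, 0.0]))
        assert res.mean_change == 0.0 and res.t == 0.0 and res.p == 1.0

    def test_unmatched_listener_rejected(self):
        az = _azbio([1.0, 2.0]).iloc[:-1]  # drop one post row
        with pytest.raises(DataError):
            paired_change_test(az)


class TestMixedModel:
    def test_null_generator_yields_null_effects(self):
        params = GeneratingParams(delta_time=0.0, delta_talker=0.0,
                                  delta_interaction=0.0, var_subject=0.0,
                                  sd_resid=0.01)
        cohort = sample_cohort(14, params, "fixture", 1)
        ds = run_study(cohort, params, rng_seed=1)
        res = fit_lmm(ds, cohort=cohort_frame(cohort), candidates=())
        for name in ("test_time", "talker", "test_time:talker"):
            assert abs(res.effects[name]["estimate"]) < 0.05
        assert res.effects["intercept"]["estimate"] == pytest.approx(25.8, abs=0.05)

    def test_reference_cell_identity(self, threshold_study, fixture_cohort_frame):
        # saturated 2x2 design: intercept equals the pre/trained cell mean
        res = fit_lmm(threshold_study, cohort=fixture_cohort_frame, candidates=())
        cell = threshold_study.tc_thresholds.query(
            "phase == 'pre' and talker == 'trained'"
        )["threshold"].mean()
        assert res.effects["intercept"]["estimate"] == pytest.approx(cell, abs=1e-6)

    def test_degenerate_variance_matches_ols(self):
        # construct data whose listener means are all equal: the REML
        # random-intercept variance provably sits on the 0 boundary, where
        # the mixed-model fixed effects coincide with OLS
        params = GeneratingParams(var_subject=0.0, sd_resid=0.0)
        cohort = sample_cohort(14, params, "fixture", 3)
        ds = run_study(cohort, params, rng_seed=3)
        thr = ds.tc_thresholds
        deltas = np.linspace(-1.5, 1.5, 14)  # sums to 0 across listeners
        pattern = {("pre", "novel"): 1.0, ("pre", "trained"): -1.0,
                   ("post", "novel"): -1.0, ("post", "trained"): 1.0}
        for d, lid in zip(deltas, thr["listener"].unique()):
            for (ph, tk), sign in pattern.items():
                m = (thr["listener"] == lid) & (thr["phase"] == ph) & (thr["talker"] == tk)
                thr.loc[m, "threshold"] += d * sign
        with pytest.warns(UserWarning, match="boundary"):
            res = fit_lmm(ds, cohort=cohort_frame(cohort), candidates=())
        df = prepost_table(ds)
        X = sm.add_constant(
            pd.DataFrame({
                "test_time": df["test_time"],
                "talker": df["talker_novel"],
                "tt": df["test_time"] * df["talker_novel"],
            })
        )
        ols = sm.OLS(df["threshold"], X).fit()
        assert res.singular
        assert res.effects["test_time"]["estimate"] == pytest.approx(ols.params["test_time"], abs=1e-4)
        assert res.effects["intercept"]["estimate"] == pytest.approx(ols.params["const"], abs=1e-4)

    def test_candidate_covariates_with_real_effect_are_retained(self, params):
        # inject a strong age effect through the random intercepts
        rng = np.random.default_rng(5)
        cohort = sample_cohort(14, params.with_overrides(var_subject=1.0), "parametric", 5)
        from dataclasses import replace

        cohort = [replace(p, b_i=p.b_i + 1.0 * (p.age - 56.0)) for p in cohort]
        ds = run_study(cohort, params, rng_seed=5)
        res = fit_lmm(ds, cohort=cohort_frame(cohort))
        assert "age" in res.effects
        assert "age" not in res.terms_dropped

    def test_design_terms_are_always_retained(self, threshold_study, fixture_cohort_frame):
        res = fit_lmm(threshold_study, cohort=fixture_cohort_frame)
        for term in ("intercept", "test_time", "talker", "test_time:talker"):
            assert term in res.effects
        assert set(res.terms_dropped) <= {"age", "duration_deafness"}

    def test_between_within_df_match_design_bookkeeping(self, threshold_study, fixture_cohort_frame):
        res = fit_lmm(threshold_study, cohort=fixture_cohort_frame,
                      candidates=(), df_method="between_within")
        # 56 obs - 14 listeners - 3 within terms = 39; intercept: 14 - 1 = 13
        for term in ("test_time", "talker", "test_time:talker"):
            assert res.effects[term]["df"] == 39.0
        assert res.effects["intercept"]["df"] == 13.0

    def test_agreement_with_lme4_reference_fit(self, threshold_study, fixture_cohort_frame):
        """Estimates, SEs, Satterthwaite df and variance components against
        an independent lme4 + lmerTest fit of the same data."""
        res = fit_lmm(threshold_study, cohort=fixture_cohort_frame, candidates=())
        df = prepost_table(threshold_study)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            df[["listener", "test_time", "talker_novel", "threshold"]].to_csv(csv, index=False)
            rcode = (
                'suppressMessages({library(lme4); library(lmerTest)});'
                f'd <- read.csv("{csv}");'
                'm <- lmerTest::lmer(threshold ~ test_time*talker_novel + (1|listener),'
                ' data=d, REML=TRUE);'
                's <- summary(m)$coefficients;'
                'vc <- as.data.frame(VarCorr(m));'
                'cat(jsonlite::toJSON(list(coef=s, vc=vc$vcov), digits=12))'
            )
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
            assert out.returncode == 0, out.stderr
            ref = json.loads(out.stdout)
        coef = np.asarray(ref["coef"], float)  # rows: est, se, df, t, p
        ours = [res.effects[k] for k in ("intercept", "test_time", "talker", "test_time:talker")]
        for row, e in zip(coef, ours):
            assert e["estimate"] == pytest.approx(row[0], abs=1e-4)
            assert e["se"] == pytest.approx(row[1], rel=1e-3)
            assert e["df"] == pytest.approx(row[2], abs=0.1)
            assert e["p"] == pytest.approx(row[4], abs=1e-3)
        assert res.var_subject_hat == pytest.approx(ref["vc"][0], rel=1e-3)
        assert res.var_resid_hat == pytest.approx(ref["vc"][1], rel=1e-3)

    def test_too_few_listeners_rejected(self, threshold_study):
        from tempotrain import StudyDataset

        one = StudyDataset(
            tc_thresholds=threshold_study.tc_thresholds.query("listener == 'S1'").copy(),
            azbio_scores=threshold_study.azbio_scores,
        )
        with pytest.raises(DataError):
            fit_lmm(one, candidates=())


class TestChangeRegression:
    def test_constant_change_gives_zero_slopes(self, params, fixture_cohort):
        p0 = params.with_overrides(azbio_sd_change=0.0)
        cohort = sample_cohort(14, p0, "fixture", 9)
        ds = run_study(cohort, p0, rng_seed=9)
        tab = change_regression(ds, cohort_frame(cohort))
        for name in ("age", "duration_deafness", "cnc_score", "tc_change"):
            assert tab.loc[name, "estimate"] == pytest.approx(0.0, abs=1e-9)
        assert tab.loc["const", "estimate"] == pytest.approx(6.3)

    def test_reports_four_predictors_plus_intercept(self, threshold_study, fixture_cohort_frame):
        tab = change_regression(threshold_study, fixture_cohort_frame)
        assert list(tab.index) == ["const", "age", "duration_deafness", "cnc_score", "tc_change"]
        assert tab["p"].between(0, 1).all()


class TestAuxiliary:
    def test_report_counts_six_correlations_seven_ttests(self, threshold_study, fixture_cohort_frame):
        rep = auxiliary_tests(threshold_study, fixture_cohort_frame)
        assert len(rep.correlations) == 6
        assert len(rep.ttests) == 7

    def test_identical_groups_give_null_t(self):
        params = GeneratingParams(sd_resid=0.0, var_subject=0.0,
                                  azbio_sd_pre=0.0, azbio_sd_change=0.0)
        cohort = sample_cohort(14, params, "fixture", 2)
        ds = run_study(cohort, params, rng_seed=2)
        rep = auxiliary_tests(ds, cohort_frame(cohort))
        tt = rep.ttests.set_index("variable")
        for v in ("pre_trained", "pre_novel", "post_trained", "post_novel",
                  "azbio_pre", "azbio_post"):
            assert tt.loc[v, "t"] == 0.0 and tt.loc[v, "p"] == 1.0

    def test_single_member_group_skipped_with_flag(self, threshold_study, fixture_cohort_frame):
        co = fixture_cohort_frame.copy()
        co["n_cis"] = 2
        rep = auxiliary_tests(threshold_study, co)
        assert rep.ttests["skipped"].all()
        assert len(rep.ttests) == 7  # still reported, flagged


class TestRecovery:
    def test_two_replicates_is_a_valid_boundary(self, params):
        rep = run_recovery(params, n_replicates=2, rng_seed=1)
        assert rep.valid
        for e in rep.entries.values():
            assert e["mc_se"] > 0

    def test_fewer_than_two_replicates_rejected(self, params):
        with pytest.raises(ValueError):
            run_recovery(params, n_replicates=1)

    def test_report_serializes(self, params):
        rep = run_recovery(params, n_replicates=3, rng_seed=2)
        assert json.dumps(rep.as_dict())
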