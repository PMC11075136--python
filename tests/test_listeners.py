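import numpy as np
import pytest

from tempotrain import (
    ConfigError,
    GeneratingParams,
    ProtocolViolationError,
    cohort_frame,
    load_demographics_fixture,
    make_responder,
    sample_cohort,
    true_threshold,
)

ENROLLED_AGES = [30, 32, 35, 49, 54, 58, 60, 63, 64, 69, 71, 76, 82, 82]


class TestGeneratingParams:
    def test_defaults_are_the_reported_effect_structure(self, params):
        assert (params.mu, params.delta_time, params.delta_talker,
                params.delta_interaction) == (25.8, 8.2, 5.2, -1.9)
        assert params.var_subject == 243.1

    def test_learning_curve_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            GeneratingParams(learning_curve=(0.5, 0.5, 0.5))

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            GeneratingParams(var_subject=-1.0)

    def test_cumulative_learning_monotone(self, params):
        cum = [params.cumulative_learning(s) for s in range(1, 6)]
        assert cum == pytest.approx([0.2, 0.4, 0.6, 0.8, 1.0])


class TestCohort:
    def test_fixture_demographics_match_enrolled_listeners(self, fixture_cohort):
        assert sorted(int(p.age) for p in fixture_cohort) == ENROLLED_AGES
        assert len(fixture_cohort) == 14
        ids = [p.id for p in fixture_cohort]
        assert ids[0] == "S1" and ids[-1] == "S14"

    def test_fixture_mode_requires_fourteen(self, params):
        with pytest.raises(ConfigError):
            sample_cohort(10, params, "fixture", 0)

    def test_unilateral_listeners_identified_from_fixture(self, fixture_cohort):
        n_cis = {p.id: p.n_cis for p in fixture_cohort}
        assert [i for i, n in n_cis.items() if n == 1] == ["S1", "S4", "S7"]

    def test_zero_subject_variance_gives_zero_intercepts(self):
        cohort = sample_cohort(14, GeneratingParams(var_subject=0.0), "fixture", 0)
        assert all(p.b_i == 0.0 for p in cohort)

    def test_random_intercept_variance_matches_generator(self, params):
        cohort = sample_cohort(10_000, params, "parametric", 12)
        v = np.var([p.b_i for p in cohort], ddof=1)
        assert abs(v - 243.1) / 243.1 < 0.05

    def test_every_parametric_profile_passes_eligibility(self, parametric_cohort):
        for p in parametric_cohort:
            assert p.moca >= 22 and p.cnc_score >= 20
            assert 30 <= p.age <= 82

    def test_azbio_change_mean_converges_to_generating_value(self, params):
        cohort = sample_cohort(10_000, params, "parametric", 5)
        changes = [p.azbio_change for p in cohort]
        assert np.mean(changes) == pytest.approx(6.3, abs=3 * 7.857 / 100)

    def test_cohort_frame_has_one_row_per_listener(self, fixture_cohort):
        df = cohort_frame(fixture_cohort)
        assert len(df) == 14 and "b_i" in df.columns

    def test_fixture_table_loads_verbatim(self):
        t1 = load_demographics_fixture()
        assert list(t1["age"]) == ENROLLED_AGES
        assert list(t1["moca"]) == [28, 28, 25, 24, 30, 30, 30, 29, 28, 28, 28, 29, 28, 27]


class TestTrueThreshold:
    def _profile(self, b=0.0, **kw):
        from tempotrain.listeners import ListenerProfile

        defaults = dict(id="x", sex="F", age=50.0, moca=28.0, duration_deafness=5.0,
                        duration_ci_use=10.0, cnc_score=80.0, n_cis=2, b_i=b,
                        azbio_pre=55.0, azbio_change=6.3)
        defaults.update(kw)
        return ListenerProfile(**defaults)

    def test_reference_cell_is_the_intercept(self, params):
        assert true_threshold(self._profile(), "pre", None, "trained", params) == 25.8

    def test_posttest_novel_cell_sums_all_effects(self, params):
        # 25.8 + 8.2 + 5.2 - 1.9, the model-implied cell mean
        assert true_threshold(self._profile(), "post", None, "novel", params) == pytest.approx(37.3)

    def test_random_intercept_is_additive(self, params):
        assert true_threshold(self._profile(b=10.0), "pre", None, "trained", params) == pytest.approx(35.8)

    def test_training_sessions_accrue_learning_fractions(self, params):
        t3 = true_threshold(self._profile(), "training", 3, "trained", params)
        assert t3 == pytest.approx(25.8 + 8.2 * 0.6)
        t5 = true_threshold(self._profile(), "training", 5, "trained", params)
        assert t5 == pytest.approx(25.8 + 8.2)

    def test_protocol_violations_rejected(self, params):
        p = self._profile()
        with pytest.raises(ProtocolViolationError):
            true_threshold(p, "training", 2, "novel", params)
        with pytest.raises(ProtocolViolationError):
            true_threshold(p, "pre", 1, "trained", params)
        with pytest.raises(ProtocolViolationError):
            true_threshold(p, "training", None, "trained", params)


class TestResponder:
    def test_noiseless_threshold_draw_is_exact(self):
        params = GeneratingParams(sd_resid=0.0, var_subject=0.0)
        cohort = sample_cohort(14, params, "fixture", 0)
        rng = np.random.default_rng(0)
        draws = {make_responder(p, "pre", None, "trained", params,
                                mode="threshold_level", rng=rng) for p in cohort}
        assert draws == {25.8}

    def test_trial_responder_is_binomial_at_threshold(self, params):
        profile = TestTrueThreshold()._profile()
        theta = true_threshold(profile, "pre", None, "trained", params)
        rng = np.random.default_rng(4)
        responder = make_responder(profile, "pre", None, "trained", params,
                                   mode="trial_level", rng=rng)
        draws = [responder(theta) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(2.5, abs=0.1)

    def test_trial_responder_mean_off_threshold(self, params):
        # 5 * logistic(3) computed independently: 5 / (1 + e^-3) = 4.7622...
        profile = TestTrueThreshold()._profile()
        theta = true_threshold(profile, "pre", None, "trained", params)
        rng = np.random.default_rng(8)
        responder = make_responder(profile, "pre", None, "trained", params,
                                   mode="trial_level", rng=rng)
        draws = [responder(theta - 20.0) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(4.76219, abs=0.05)

    def test_unknown_mode_rejected(self, params, fixture_cohort):
        with pytest.raises(ConfigError):
            make_responder(fixture_cohort[0], "pre", None, "trained", params, mode="oracle")
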