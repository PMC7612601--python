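"""Trial simulation: data generation, adaptive/fixed runs, operating characteristics."""

import dataclasses
import warnings

import numpy as np
import pytest

import swadapt as sw
from swadapt.designs import NEVER
from swadapt.simulate import _replicate_rng


def _quiet_policy(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sw.AdaptationPolicy(**kw)


class TestRandomEffects:
    def test_pure_residual_means(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  vc=sw.VarianceComponents(sigma2_e=2.0))
        draws = np.stack([sw.draw_random_effects(cfg, _replicate_rng(0, r)).noise()
                          for r in range(4000)])
        v = draws.var(axis=0).mean()
        assert v == pytest.approx(2.0 / cfg.design.m, rel=0.05)
        # independence across periods
        corr = np.corrcoef(draws[:, 0, 0], draws[:, 0, 1])[0, 1]
        assert abs(corr) < 0.05

    @pytest.mark.parametrize("cohort,sigma2_s", [
        (sw.Cohort.CROSS_SECTIONAL, 0.0), (sw.Cohort.CLOSED_COHORT, 11.725)])
    def test_empirical_covariance_matches_analytic_block(self, cohort, sigma2_s):
        X = sw.AllocationMatrix.from_string("011,001,000")
        design = sw.TrialDesign(C=3, P=3, m=5, cohort=cohort, X_init=X,
                                alpha=0.05, beta=0.2, delta=1.0)
        vc = sw.VarianceComponents(sigma2_c=0.4, sigma2_pi=0.2,
                                   sigma2_s=sigma2_s, sigma2_e=1.5)
        cfg = sw.ScenarioConfig(design=design, vc=vc,
                                policy=_quiet_policy(w=0.5), theta_true=0.0,
                                n_reps=1, seed=0)
        draws = np.stack([sw.draw_random_effects(cfg, _replicate_rng(1, r)).noise()[0]
                          for r in range(50_000)])
        emp = np.cov(draws, rowvar=False)
        block = sw.build_covariance(vc, cohort, 3, m=5)
        assert np.allclose(emp, block, rtol=0.02, atol=0.02 * block.max())

    def test_closed_cohort_adds_individual_covariance(self):
        # across-period covariance of means: cross-sectional sigma2_c only,
        # closed cohort sigma2_c + sigma2_s / m
        X = sw.AllocationMatrix.from_string("01,00")
        vc = sw.VarianceComponents(sigma2_c=0.3, sigma2_s=1.0, sigma2_e=1.0)
        closed = sw.build_covariance(vc, sw.Cohort.CLOSED_COHORT, 2, m=4)
        assert closed[0, 1] == pytest.approx(0.3 + 1.0 / 4)
        cross = sw.build_covariance(dataclasses.replace(vc, sigma2_s=0.0),
                                    sw.Cohort.CROSS_SECTIONAL, 2, m=4)
        assert cross[0, 1] == pytest.approx(0.3)


class TestRealizeResponses:
    def test_null_effect_ignores_allocation(self, small_config):
        draw = sw.draw_random_effects(small_config, _replicate_rng(2, 0))
        X0 = small_config.design.X_init
        X1 = sw.AllocationMatrix(np.ones_like(X0.entries))
        assert np.array_equal(sw.realize_responses(draw, X0, range(1, 5), 0.0),
                              sw.realize_responses(draw, X1, range(1, 5), 0.0))

    def test_effect_shift_is_exact(self, small_config):
        draw = sw.draw_random_effects(small_config, _replicate_rng(2, 1))
        X = small_config.design.X_init
        y0 = sw.realize_responses(draw, X, range(1, 5), 0.2)
        y1 = sw.realize_responses(draw, X, range(1, 5), 0.7)
        assert np.allclose(y1 - y0, 0.5 * X.entries)

    def test_period_out_of_range(self, small_config):
        draw = sw.draw_random_effects(small_config, _replicate_rng(2, 2))
        with pytest.raises(ValueError, match="period"):
            sw.realize_responses(draw, small_config.design.X_init, [5], 0.0)

    def test_near_deterministic_limit_recovers_effect(self, small_config):
        vc = sw.VarianceComponents(sigma2_c=1e-14, sigma2_e=1e-12)
        cfg = dataclasses.replace(small_config, vc=vc, theta_true=0.8)
        res = sw.run_fixed_trial(cfg, _replicate_rng(3, 0))
        assert res.theta_hat_final == pytest.approx(0.8, abs=1e-6)


class TestFixedTrial:
    def test_initially_planned_proportion(self, tds1):
        res = sw.run_fixed_trial(dataclasses.replace(tds1, theta_true=0.0),
                                 _replicate_rng(4, 0))
        assert res.proportion == 98 / 180
        assert res.X_final == tds1.design.X_init
        assert res.interim_Z == ()

    def test_estimator_calibration(self, tds2):
        # empirical variance of theta_hat matches 1/I and bias is null
        cfg = dataclasses.replace(tds2, theta_true=0.2, n_reps=10_000, seed=5)
        engine = sw.TrialEngine(cfg)
        th = np.array([engine.run_fixed(_replicate_rng(cfg.seed, r), 0.2).theta_hat_final
                       for r in range(cfg.n_reps)])
        info = sw.information(cfg.design.X_init, 5, cfg.design, cfg.vc)
        assert th.var() == pytest.approx(1 / info, rel=0.05)
        assert abs(th.mean() - 0.2) < 3 * th.std() / np.sqrt(len(th))

    def test_power_consistent_with_analytic(self, tds2):
        cfg = dataclasses.replace(tds2, theta_true=0.2, n_reps=4000, seed=6)
        oc = sw.simulate_scenario(cfg, adaptive=False)
        expected = sw.hh_power(cfg.design, cfg.vc, theta=0.2)
        assert abs(oc.erp - expected) < 3 * oc.mc_se["erp"]


class TestAdaptiveTrial:
    def test_degenerate_adaptation_reproduces_fixed_trial(self, small_config):
        X0 = small_config.design.X_init
        frozen = _quiet_policy(w=0.5, eta=0.0, gamma=2.5,
                               admissible=lambda M: M == X0)
        design = dataclasses.replace(small_config.design,
                                     interim_periods=(small_config.design.P - 1,))
        cfg = dataclasses.replace(small_config, design=design, policy=frozen,
                                  theta_true=0.5)
        for r in range(20):
            ra = sw.run_adaptive_trial(cfg, _replicate_rng(cfg.seed, r))
            rf = sw.run_fixed_trial(cfg, _replicate_rng(cfg.seed, r))
            assert ra.X_final == X0
            assert ra.theta_hat_final == rf.theta_hat_final
            assert ra.reject == rf.reject

    def test_forced_interim_statistic_reproduces_worked_example(self, tds2):
        cfg = dataclasses.replace(tds2, theta_true=0.0, seed=9)
        res = sw.run_adaptive_trial(cfg, _replicate_rng(cfg.seed, 0),
                                    z_override={3: 1.0})
        assert res.X_final.to_string() == "01111,00111,00011,00011"
        assert res.proportion == 0.55

    def test_power_priority_weight_fixes_the_rollout(self, tds1):
        cfg = dataclasses.replace(
            tds1, policy=_quiet_policy(w=999 / 1000, eta=0.0, gamma=2.5),
            n_reps=200)
        engine = sw.TrialEngine(cfg)
        for theta in (0.0, 0.24):
            props = {sw.run_adaptive_trial(dataclasses.replace(cfg, theta_true=theta),
                                           _replicate_rng(cfg.seed, r),
                                           engine=engine).proportion
                     for r in range(60)}
            assert props == {0.45}

    def test_realized_proportion_within_reachable_bounds(self, tds1):
        cfg = dataclasses.replace(tds1, theta_true=0.24, n_reps=1)
        engine = sw.TrialEngine(cfg)
        p1 = cfg.design.interim_periods[0]
        X = cfg.design.X_init
        lo_M = sw.build_continuation(X, p1, [NEVER] * 14)
        hi_M = sw.build_continuation(X, p1, [p1 + 1] * 14)
        lo, hi = (sw.intervention_proportion(lo_M), sw.intervention_proportion(hi_M))
        for r in range(50):
            res = sw.run_adaptive_trial(cfg, _replicate_rng(17, r), engine=engine)
            assert lo <= res.proportion <= hi

    def test_interim_without_exposure_raises(self, small_config):
        design = dataclasses.replace(
            small_config.design,
            X_init=sw.AllocationMatrix.from_string("0011,0011,0001,0000"),
            interim_periods=(1,))
        cfg = dataclasses.replace(small_config, design=design)
        with pytest.raises(sw.SingularDesignError):
            sw.run_adaptive_trial(cfg, _replicate_rng(0, 0))

    def test_observation_level_mode_agrees_distributionally(self, small_config):
        # same machinery runs at observation granularity; spot-check one
        # replicate produces a finite, plausible result and the same X paths
        # are reachable
        cfg = dataclasses.replace(small_config, analysis_mode="observation_level",
                                  theta_true=0.5)
        res = sw.run_adaptive_trial(cfg, _replicate_rng(21, 0))
        assert np.isfinite(res.theta_hat_final)
        sw.validate_allocation(res.X_final.entries, 4, 4)


class TestOperatingCharacteristics:
    def test_identical_results_have_zero_spread(self, tds1):
        r = sw.TrialResult(reject=True, theta_hat_final=0.3,
                           X_final=tds1.design.X_init, proportion=98 / 180,
                           interim_Z=(1.0,))
        oc = sw.estimate_operating_characteristics([r] * 10, theta_true=0.24)
        assert oc.esdcp == 0.0
        assert oc.prop_pmf == {98 / 180: 1.0}
        assert oc.erp == 1.0

    def test_rmse_decomposition_identity(self, tds2):
        cfg = dataclasses.replace(tds2, theta_true=0.2, n_reps=300, seed=12)
        engine = sw.TrialEngine(cfg)
        results = [engine.run_adaptive(_replicate_rng(cfg.seed, r), 0.2)
                   for r in range(cfg.n_reps)]
        oc = sw.estimate_operating_characteristics(results, 0.2)
        th = np.array([r.theta_hat_final for r in results])
        assert oc.ermse**2 == pytest.approx(oc.eb**2 + th.var(ddof=0), rel=1e-12)

    def test_pmf_sums_to_one_and_mean_matches_eacp(self, tds1):
        cfg = dataclasses.replace(tds1, theta_true=0.24, n_reps=200, seed=13)
        oc = sw.simulate_scenario(cfg)
        assert sum(oc.prop_pmf.values()) == pytest.approx(1.0)
        assert sum(p * w for p, w in oc.prop_pmf.items()) == pytest.approx(oc.eacp)
        assert oc.mean_X.shape == (20, 9)
        assert oc.mean_X.mean() == pytest.approx(oc.eacp)

    def test_seed_reproducibility_bit_exact(self, tds1):
        cfg = dataclasses.replace(tds1, theta_true=0.24, n_reps=100, seed=14)
        a = sw.simulate_scenario(cfg)
        b = sw.simulate_scenario(cfg)
        assert a.erp == b.erp and a.eacp == b.eacp and a.ermse == b.ermse
        assert a.prop_pmf == b.prop_pmf
        assert np.array_equal(a.mean_X, b.mean_X)


class TestBuiltinScenarios:
    def test_error_rate_targets(self, scenarios):
        d1 = scenarios["TDS1"].design
        assert (d1.alpha, d1.beta, d1.delta) == (0.05, 0.2, 0.24)
        d3 = scenarios["TDS3"].design
        assert (d3.alpha, d3.delta) == (0.025, 2.0)
        assert scenarios["TDS3"].design.cohort is sw.Cohort.CLOSED_COHORT

    def test_dimensions_and_components(self, scenarios):
        d1, d2, d3 = (scenarios[k].design for k in ("TDS1", "TDS2", "TDS3"))
        assert (d1.C, d1.P, d1.m) == (20, 9, 7)
        assert (d2.C, d2.P, d2.m) == (4, 5, 70)
        assert (d3.C, d3.P, d3.m) == (12, 4, 10)
        v3 = scenarios["TDS3"].vc
        assert (v3.sigma2_c, v3.sigma2_pi, v3.sigma2_s, v3.sigma2_e) == \
            (7.425, 0.825, 11.725, 5.025)

    def test_initial_matrices_valid_and_start_in_control(self, scenarios):
        for cfg in scenarios.values():
            X = cfg.design.X_init
            sw.validate_allocation(X.entries, cfg.design.C, cfg.design.P)
            assert np.all(X.entries[:, 0] == 0)

    def test_switch_schedules(self, scenarios):
        h1 = sw.switch_time_histogram(scenarios["TDS1"].design.X_init)
        assert h1.counts == {2: 3, 3: 3, 4: 3, 5: 3, 6: 2, 7: 2, 8: 2, 9: 2}
        h3 = sw.switch_time_histogram(scenarios["TDS3"].design.X_init)
        assert h3.counts == {2: 4, 3: 4, 4: 4}
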