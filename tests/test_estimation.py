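"""ML fitting, Wald and sandwich inference, likelihood-ratio tests, AIC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import rxmix as rx
from rxmix.distributions import ComponentParams, DomainError
from rxmix.estimation import (
    FitResult,
    _fd_gradient,
    _safe_negloglik,
    param_names,
    param_transforms,
)
from rxmix.joint_model import ModelSpec, ObservationSet, ParamSet


class TestPacking:
    def test_round_trip_on_reference_truth(self, family):
        spec, truth = rx.study_truth(family)
        back = rx.unpack(spec, rx.pack(spec, truth))
        for a, b in zip(back.components, truth.components):
            np.testing.assert_allclose(a.params, b.params, rtol=1e-12)
        np.testing.assert_allclose(back.beta, truth.beta)
        np.testing.assert_allclose(back.gamma, truth.gamma)

    def test_even_mixture_packs_to_zero_weight_coordinate(self):
        spec = ModelSpec(family="lognormal", m=2)
        ps = ParamSet(
            components=[ComponentParams("lognormal", (0, 1)), ComponentParams("lognormal", (1, 1))],
            beta=[[0.0]],
            gamma=[0.0, 0.0],
        )
        theta = rx.pack(spec, ps)
        i = param_names(spec).index("alpha_logit")
        assert theta[i] == 0.0  # alpha = 1/2 <-> logit 0

    @settings(derandomize=True, max_examples=50)
    @given(v=st.lists(st.floats(-3, 3), min_size=8, max_size=8))
    def test_pack_unpack_idempotent(self, v):
        spec = ModelSpec(family="bass", m=2, n_covariates=1)  # 8 free parameters
        theta = np.asarray(v)
        packed = rx.pack(spec, rx.unpack(spec, theta))
        np.testing.assert_allclose(packed, theta, atol=1e-12)

    def test_length_mismatch_is_structural_error(self):
        spec = ModelSpec(family="bass", m=2)
        with pytest.raises(DomainError):
            rx.unpack(spec, np.zeros(5))


class TestSequentialInit:
    def test_single_component_data_recovered_by_marginal_stage(self, rng):
        # all mass in one wave: the dominant fitted component should land
        # near the generating parameters
        cp = ComponentParams("lognormal", (1.09, 0.0274))
        y = rx.sample(cp, 400, rng)
        obs = ObservationSet(time=y, event=rng.integers(0, 2, size=400))
        spec = ModelSpec(family="lognormal", m=2)
        with np.errstate(all="ignore"):
            start = rx.initialize_sequential(spec, obs)
        w = rx.mixture_weights(spec, start, n=1)[0]
        dominant = start.components[int(np.argmax(w))]
        assert dominant.params[0] == pytest.approx(1.09, abs=0.05)

    def test_well_separated_modes_are_bracketed(self, small_dataset):
        spec, truth, obs = small_dataset
        start = rx.initialize_sequential(spec, obs)
        modes = sorted(rx.mode(c) for c in start.components)
        assert 0.3 < modes[0] < 1.8
        assert 2.0 < modes[1] < 4.0

    def test_gamma_stage_reproduces_the_event_rate(self, rng):
        # with X independent of Y, the fitted behavior stage should give a
        # predicted event probability matching the empirical rate
        cp = ComponentParams("lognormal", (0.0, 0.01))
        y = rx.sample(cp, 300, rng)
        x = (rng.uniform(size=300) < 0.25).astype(int)
        obs = ObservationSet(time=y, event=x)
        spec = ModelSpec(family="lognormal", m=2)
        with np.errstate(all="ignore"):
            start = rx.initialize_sequential(spec, obs)
        predicted = rx.event_probability(spec, start, obs.time).mean()
        assert predicted == pytest.approx(x.mean(), abs=0.03)


class TestFitMle:
    def test_fit_from_truth_on_large_sample_dominates_truth(self, rng):
        spec, truth = rx.study_truth("lognormal")
        cfg = rx.SimConfig(spec=spec, truth=truth, n=10_000, seed=3)
        obs = rx.generate_base(cfg, rng)
        fit = rx.fit_mle(spec, obs, start=truth)
        assert fit.converged
        assert fit.loglik >= rx.joint_loglik(spec, truth, obs) - 1e-6
        se = fit.se()
        theta_true = rx.pack(spec, truth)
        assert np.all(np.abs(fit.theta - theta_true) <= 3 * se)

    def test_gradient_vanishes_at_reported_optimum(self, rng):
        spec, truth = rx.study_truth("lognormal")
        cfg = rx.SimConfig(spec=spec, truth=truth, n=30, seed=11)
        obs = rx.generate_base(cfg, rng)
        with np.errstate(all="ignore"):
            fit = rx.fit_mle(spec, obs)
        g = _fd_gradient(_safe_negloglik(spec, obs), fit.theta)
        assert np.max(np.abs(g)) < 1e-3

    def test_joint_fit_improves_on_sequential_start(self, small_dataset):
        spec, truth, obs = small_dataset
        start = rx.initialize_sequential(spec, obs)
        fit = rx.fit_mle(spec, obs, start=start)
        assert fit.loglik >= rx.joint_loglik(spec, start, obs) - 1e-8

    def test_refit_from_estimates_is_stationary(self, small_dataset):
        spec, truth, obs = small_dataset
        fit1 = rx.fit_mle(spec, obs)
        fit2 = rx.fit_mle(spec, obs, start=fit1.params)
        assert abs(fit2.loglik - fit1.loglik) < 1e-6

    def test_components_reported_in_canonical_order(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        modes = [rx.mode(c) for c in fit.params.components]
        assert modes == sorted(modes)

    def test_single_population_data_flags_boundary_not_crash(self, rng):
        cp = ComponentParams("weibull", (3.0, 2.0))
        y = rx.sample(cp, 250, rng)
        obs = ObservationSet(time=y, event=rng.integers(0, 2, size=250))
        spec = ModelSpec(family="weibull", m=2)
        with np.errstate(all="ignore"):
            fit = rx.fit_mle(spec, obs)  # must not raise
        assert np.isfinite(fit.loglik)


class TestWaldCI:
    def test_alpha_interval_stays_inside_unit_interval(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        s = fit.summary()
        assert 0.0 < s.loc["alpha", "lower"] < s.loc["alpha", "upper"] < 1.0

    def test_positive_parameters_have_positive_intervals(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        ci = rx.wald_ci(fit)
        pos = [i for i, t in enumerate(param_transforms(spec)) if t == "log"]
        assert np.all(ci[pos, 0] > 0)

    def test_zero_se_degenerates_to_point(self):
        spec = ModelSpec(family="lognormal", m=2)
        _, truth = rx.study_truth("lognormal")
        theta = rx.pack(spec, truth)
        fit = FitResult(
            spec=spec, params=truth, theta=theta, loglik=0.0,
            vcov_naive=np.zeros((spec.n_params, spec.n_params)),
            converged=True, n_obs=100, grad_norm=0.0,
            names=param_names(spec), transforms=param_transforms(spec),
        )
        ci = rx.wald_ci(fit)
        from rxmix.estimation import _back
        np.testing.assert_allclose(ci[:, 0], _back(theta, fit.transforms))
        np.testing.assert_allclose(ci[:, 1], ci[:, 0])

    def test_estimate_between_bounds(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        s = fit.summary(level=0.9)
        assert np.all(s["lower"] <= s["estimate"] + 1e-12)
        assert np.all(s["estimate"] <= s["upper"] + 1e-12)


class TestRobustVcov:
    def test_singleton_clusters_match_no_labels(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        V1 = rx.robust_vcov(fit, obs)  # no labels: each row its own cluster
        obs2 = ObservationSet(time=obs.time, event=obs.event,
                              cluster=np.arange(obs.n))
        V2 = rx.robust_vcov(fit, obs2)
        np.testing.assert_allclose(V1, V2, rtol=1e-10)

    def test_independent_data_robust_close_to_naive(self, rng):
        spec, truth = rx.study_truth("lognormal")
        cfg = rx.SimConfig(spec=spec, truth=truth, n=4000, seed=5)
        obs = rx.generate_base(cfg, rng)
        fit = rx.fit_mle(spec, obs)
        rx.robust_vcov(fit, obs)
        ratio = fit.se(robust=True) / fit.se()
        assert np.all(np.abs(ratio - 1) < 0.15)

    def test_invariant_to_observation_order_and_label_names(self, small_dataset, rng):
        spec, truth, obs = small_dataset
        labels = np.repeat(np.arange(obs.n // 10), 10)
        obs_a = ObservationSet(time=obs.time, event=obs.event, cluster=labels)
        fit = rx.fit_mle(spec, obs_a)
        Va = rx.robust_vcov(fit, obs_a)
        perm = rng.permutation(obs.n)
        renamed = np.array([f"grp_{g}" for g in labels[perm]])
        obs_b = ObservationSet(time=obs.time[perm], event=obs.event[perm], cluster=renamed)
        Vb = rx.robust_vcov(fit, obs_b)  # same optimum, reshuffled data
        np.testing.assert_allclose(Va, Vb, rtol=1e-8, atol=1e-12)

    def test_single_cluster_rejected(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        one = ObservationSet(time=obs.time, event=obs.event,
                             cluster=np.zeros(obs.n, dtype=int))
        with pytest.raises(DomainError):
            rx.robust_vcov(fit, one)


class TestModelComparison:
    def test_self_comparison_is_null(self, small_dataset):
        spec, truth, obs = small_dataset
        fit = rx.fit_mle(spec, obs)
        stat, df, p = rx.lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_covariate_with_real_effect_is_detected(self):
        # effect size 1 on the mixture-weight logit at n=100
        spec, truth = rx.study_truth("lognormal", covariate=True)
        null_spec = ModelSpec(family="lognormal", m=2)
        hits = 0
        reps = 40
        for rng in [np.random.default_rng(s) for s in np.random.SeedSequence(77).spawn(reps)]:
            cfg = rx.SimConfig(spec=spec, truth=truth, n=100, design="covariate", seed=0)
            obs = rx.generate_covariate(cfg, rng)
            obs_null = ObservationSet(time=obs.time, event=obs.event)
            fit_alt = rx.fit_mle(spec, obs)
            fit_null = rx.fit_mle(null_spec, obs_null)
            if not (fit_alt.converged and fit_null.converged):
                continue
            _, _, p = rx.lrt(fit_null, fit_alt)
            hits += p < 0.05
        assert hits / reps > 0.5

    def test_aic_arithmetic(self):
        spec = ModelSpec(family="lognormal", m=2, n_covariates=2)  # 9 free params
        assert spec.n_params == 9
        _, truth = rx.study_truth("lognormal")
        fit = FitResult(
            spec=spec, params=truth, theta=np.zeros(9), loglik=-540.9,
            vcov_naive=np.eye(9), converged=True, n_obs=305, grad_norm=0.0,
        )
        assert rx.aic(fit) == pytest.approx(1099.8)

    def test_extra_parameter_without_gain_costs_two(self):
        spec_small = ModelSpec(family="lognormal", m=2)
        spec_big = ModelSpec(family="lognormal", m=2, n_covariates=1)
        _, truth = rx.study_truth("lognormal")
        mk = lambda sp, ll: FitResult(
            spec=sp, params=truth, theta=np.zeros(sp.n_params), loglik=ll,
            vcov_naive=np.eye(sp.n_params), converged=True, n_obs=100, grad_norm=0.0,
        )
        assert rx.aic(mk(spec_big, -200.0)) - rx.aic(mk(spec_small, -200.0)) == pytest.approx(2.0)

    def test_equal_complexity_aic_ranking_equals_loglik_ranking(self, small_dataset):
        spec, truth, obs = small_dataset
        fits = [rx.fit_mle(ModelSpec(family=f, m=2), obs) for f in ("bass", "lognormal", "weibull")]
        by_ll = sorted(fits, key=lambda f: -f.loglik)
        by_aic = sorted(fits, key=lambda f: rx.aic(f))
        assert [f.spec.family for f in by_ll] == [f.spec.family for f in by_aic]
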