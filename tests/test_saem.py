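"""SAEM engine: recovery, determinism, likelihood oracles, EBEs, shrinkage, SEs."""

import math
from dataclasses import replace

import numpy as np
import pytest

from gabapk.cohort import (
    CohortConfig, generate_cohort, generate_design, rich_design,
    simulate_concentrations,
)
from gabapk.population import (
    ErrorModelSpec, FixedEffects, PopulationModelSpec, RandomEffectsSpec,
)
from gabapk.saem import (
    SAEMSettings, convergence_assessment, empirical_bayes,
    fit_saem, loglik_importance_sampling, loglik_quadrature, shrinkage,
    standard_errors,
)


def _simulate(truth, n_subjects, seed, offsets=(1.0, 3.0, 6.0, 8.0)):
    cfg = CohortConfig(n_subjects=n_subjects, seed=seed)
    designed = rich_design(generate_cohort(cfg), sample_offsets=offsets)
    return simulate_concentrations(designed, truth, seed=seed + 1000)


class TestFit:
    def test_noise_free_recovery_within_one_percent(self, truth_spec):
        clean_truth = replace(
            truth_spec,
            random_effects=RandomEffectsSpec(1e-3, 1e-3),
            error=ErrorModelSpec(kind="constant", a=0.01),
        )
        ds, _ = _simulate(clean_truth, 40, seed=3,
                          offsets=(0.5, 1, 2, 3, 4, 6, 8))
        start = replace(
            truth_spec,
            random_effects=RandomEffectsSpec(0.3, 0.3),
            error=ErrorModelSpec(kind="constant", a=1.0),
        )
        fit = fit_saem(ds, start, SAEMSettings(seed=5))
        assert fit.estimates["v_pop"] == pytest.approx(44.61, rel=0.01)
        assert fit.estimates["cl_pop"] == pytest.approx(5.73, rel=0.01)
        assert fit.estimates["beta_cl_SCR"] == pytest.approx(-0.89, abs=0.01)

    def test_identical_seed_bit_identical_trajectory(self, rich_dataset,
                                                     truth_spec, fast_settings):
        ds, _ = rich_dataset
        f1 = fit_saem(ds, truth_spec, fast_settings)
        f2 = fit_saem(ds, truth_spec, fast_settings)
        for k in f1.trajectory:
            assert np.array_equal(f1.trajectory[k], f2.trajectory[k])

    def test_fixed_parameter_untouched(self, rich_dataset, truth_spec,
                                       fast_settings):
        ds, _ = rich_dataset
        fit = fit_saem(ds, truth_spec, fast_settings)
        assert np.all(fit.trajectory["ka_pop"] == 0.778)
        assert fit.spec.fixed.ka_pop == 0.778

    def test_all_fixed_spec_rejected(self, rich_dataset):
        ds, _ = rich_dataset
        degenerate = PopulationModelSpec(
            random_effects=RandomEffectsSpec(0.0, 0.0),
            fixed_parameters=("v", "cl", "ka", "tlag"),
        )
        with pytest.raises(ValueError, match="fixed"):
            fit_saem(ds, degenerate, SAEMSettings(n_burnin=5, n_smooth=5))


class TestLikelihood:
    def test_importance_sampling_matches_quadrature(self, small_tdm_dataset,
                                                    truth_spec):
        ds, _ = small_tdm_dataset
        q = loglik_quadrature(ds, truth_spec, nodes=32)
        i = loglik_importance_sampling(ds, truth_spec, n_samples=2000, seed=7)
        assert abs(i.ofv - q.ofv) < 0.5

    def test_quadrature_node_convergence(self, truth_spec):
        # 1-random-effect toy with a moderate omega converges fast in nodes
        spec = replace(truth_spec,
                       random_effects=RandomEffectsSpec(0.0, 0.3))
        cfg = CohortConfig(n_subjects=8, seed=2)
        designed = generate_design(generate_cohort(cfg), cfg)
        ds, _ = simulate_concentrations(designed, spec, seed=3)
        o32 = loglik_quadrature(ds, spec, nodes=32).ofv
        o64 = loglik_quadrature(ds, spec, nodes=64).ofv
        assert abs(o64 - o32) < 1e-6

    def test_zero_omega_collapses_to_observation_density(self, truth_spec):
        from gabapk.population import individual_parameters, observation_loglik
        from gabapk.structural import concentration_first_order
        spec = replace(truth_spec, random_effects=RandomEffectsSpec(0.0, 0.0))
        cfg = CohortConfig(n_subjects=6, seed=4)
        designed = generate_design(generate_cohort(cfg), cfg)
        ds, _ = simulate_concentrations(designed, spec, seed=5)
        q = loglik_quadrature(ds, spec)
        direct = 0.0
        for s in ds.subjects:
            p = individual_parameters(spec, s.covariates)
            for o in s.observations:
                f = concentration_first_order(o.time, s.doses, p)
                direct += observation_loglik(o.concentration, f, spec.error)
        assert q.ofv == pytest.approx(-2 * direct, abs=1e-8)

    def test_one_observation_gaussian_toy_matches_analytic_convolution(self):
        # ka -> huge and one sample makes y | eta_v exactly Gaussian in
        # exp(-eta) scale; with tiny omega the marginal is analytically a
        # Gaussian convolution, cross-checked by a fine-grid integral
        from scipy.integrate import quad
        from scipy.stats import norm
        from gabapk.dataset import (CovariateRecord, DoseEvent, Observation,
                                    PKDataset, Subject)
        cov = CovariateRecord.from_raw(age=50, sex="male", race="white",
                                       weight=80, height=178, scr=1.3,
                                       fpg=100, diabetes=False)
        subj = Subject(id="1", doses=[DoseEvent(0.0, 300.0)],
                       observations=[Observation(6.0, 3.0)], covariates=cov)
        ds = PKDataset(subjects=[subj])
        spec = PopulationModelSpec(
            fixed=FixedEffects(v_pop=44.61, cl_pop=5.73),
            random_effects=RandomEffectsSpec(omega_v=0.0, omega_cl=0.4),
            error=ErrorModelSpec(kind="constant", a=1.0),
        )
        q = loglik_quadrature(ds, spec, nodes=64)

        from gabapk.population import individual_parameters
        from gabapk.structural import concentration_first_order

        def integrand(eta):
            p = individual_parameters(spec, cov, {"cl": eta})
            f = concentration_first_order(6.0, subj.doses, p)
            return norm.pdf(3.0, loc=f, scale=1.0) * norm.pdf(eta, scale=0.4)

        li, _ = quad(integrand, -4, 4, limit=200)
        assert q.ofv == pytest.approx(-2 * math.log(li), abs=1e-4)

    def test_information_criteria_identities(self, small_tdm_dataset,
                                             truth_spec):
        ds, _ = small_tdm_dataset
        lik = loglik_importance_sampling(ds, truth_spec, n_samples=200, seed=1)
        assert lik.aic == pytest.approx(lik.ofv + 2 * lik.n_parameters)
        assert lik.bic == pytest.approx(
            lik.ofv + lik.n_parameters * math.log(ds.n_observations))

    def test_mc_se_scales_with_sample_size(self, small_tdm_dataset,
                                           truth_spec):
        ds, _ = small_tdm_dataset
        se_small = np.mean([
            loglik_importance_sampling(ds, truth_spec, n_samples=250,
                                       seed=s).mc_se
            for s in range(4)
        ])
        se_large = np.mean([
            loglik_importance_sampling(ds, truth_spec, n_samples=1000,
                                       seed=s).mc_se
            for s in range(4)
        ])
        # doubling twice should halve the SE, allow generous slack
        assert se_large < se_small * 0.75


class TestEBE:
    def test_uninformative_subject_shrinks_to_zero(self, truth_spec):
        huge_noise = replace(truth_spec,
                             error=ErrorModelSpec(kind="constant", a=500.0))
        cfg = CohortConfig(n_subjects=4, seed=8)
        designed = generate_design(generate_cohort(cfg), cfg)
        ds, _ = simulate_concentrations(designed, huge_noise, seed=9)
        fit = fit_saem(ds, huge_noise,
                       SAEMSettings(n_burnin=20, n_smooth=10, seed=1))
        fit.spec = huge_noise  # evaluate EBEs at the generating spec
        ebes = empirical_bayes(fit, ds)
        assert np.all(np.abs(ebes) < 0.05)

    def test_dense_low_noise_data_recovers_simulated_etas(self, truth_spec):
        low_noise = replace(truth_spec,
                            error=ErrorModelSpec(kind="constant", a=0.05))
        cfg = CohortConfig(n_subjects=12, seed=10)
        designed = rich_design(generate_cohort(cfg),
                               sample_offsets=(0.5, 1, 2, 3, 5, 8))
        ds, truth = simulate_concentrations(designed, low_noise, seed=11)
        fit = fit_saem(ds, low_noise,
                       SAEMSettings(n_burnin=20, n_smooth=10, seed=2))
        fit.spec = low_noise
        ebes = empirical_bayes(fit, ds)
        # Cl is sharply identified by the steady-state level; V is flatter
        # for high-V subjects (small peak-trough swing), so the V check is
        # on the bulk of subjects rather than the worst case
        assert np.allclose(ebes[:, 1], truth.etas["cl"], atol=0.1)
        err_v = np.abs(ebes[:, 0] - truth.etas["v"])
        assert np.median(err_v) < 0.05
        assert np.max(err_v) < 0.3

    def test_ebe_population_mean_near_zero(self, rich_dataset, truth_spec):
        ds, _ = rich_dataset
        fit = fit_saem(ds, truth_spec,
                       SAEMSettings(n_burnin=100, n_smooth=80, seed=3))
        ebes = empirical_bayes(fit, ds)
        assert np.all(np.abs(ebes.mean(axis=0)) < 0.25)


class TestShrinkage:
    def test_definitional_cases(self):
        ebes = np.random.default_rng(0).normal(0, 0.3, size=(500, 1))
        s = shrinkage(ebes, [np.std(ebes[:, 0], ddof=1)])
        assert s[0] == pytest.approx(0.0, abs=1e-9)
        s100 = shrinkage(np.zeros((100, 1)), [0.5])
        assert s100[0] == pytest.approx(100.0)
        assert shrinkage(ebes, [0.0]) == [None]

    def test_rich_design_shrinkage_moderate(self, rich_dataset, truth_spec,
                                            fast_settings):
        ds, _ = rich_dataset
        fit = fit_saem(ds, truth_spec, fast_settings)
        empirical_bayes(fit, ds)
        omegas = [fit.spec.random_effects.omega(p)
                  for p in fit.ebe_parameters]
        shr = shrinkage(fit.ebes, omegas)
        # 4 samples/subject leaves limited but real individual information
        assert all(s is not None and s < 60.0 for s in shr)


class TestStandardErrors:
    def test_rse_definition_and_sqrt_n_scaling(self, truth_spec):
        ds_small, _ = _simulate(truth_spec, 50, seed=21)
        ds_large, _ = _simulate(truth_spec, 200, seed=22)
        settings = SAEMSettings(n_burnin=150, n_smooth=100, seed=4)
        fit_s = fit_saem(ds_small, truth_spec, settings)
        fit_l = fit_saem(ds_large, truth_spec, settings)
        se_s, rse_s, _ = standard_errors(fit_s, ds_small, seed=1,
                                         n_samples=300)
        se_l, rse_l, _ = standard_errors(fit_l, ds_large, seed=1,
                                         n_samples=300)
        # RSE is 100 * SE / |estimate| by definition
        for k in se_s:
            if np.isfinite(se_s[k]):
                assert rse_s[k] == pytest.approx(
                    100 * se_s[k] / abs(fit_s.estimates[k]))
        # quadrupling the cohort should roughly halve the fixed-effect SEs
        ratio = se_l["cl_pop"] / se_s["cl_pop"]
        assert 0.3 < ratio < 0.8

    def test_fixed_parameters_carry_no_se(self, rich_dataset, truth_spec,
                                          fast_settings):
        ds, _ = rich_dataset
        fit = fit_saem(ds, truth_spec, fast_settings)
        se, _, _ = standard_errors(fit, ds, seed=2, n_samples=200)
        assert "ka_pop" not in se


class TestConvergenceAssessment:
    def test_rich_data_stable_and_deterministic(self, rich_dataset,
                                                truth_spec):
        ds, _ = rich_dataset
        settings = SAEMSettings(n_burnin=120, n_smooth=80)
        rep = convergence_assessment(ds, truth_spec, settings, n_runs=3,
                                     base_seed=5)
        assert rep["failures"] == []
        for k in ("v_pop", "cl_pop"):
            assert rep["parameters"][k]["relative_spread"] < 0.25
        rep2 = convergence_assessment(ds, truth_spec, settings, n_runs=3,
                                      base_seed=5)
        assert rep == rep2
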