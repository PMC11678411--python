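"""Residual diagnostics, VPC bands and bootstrap behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from gabapk.cohort import (
    CohortConfig, generate_cohort, rich_design, simulate_concentrations,
)
from gabapk.dataset import PKDataset
from gabapk.diagnostics import bootstrap, residuals, vpc
from gabapk.population import ErrorModelSpec, RandomEffectsSpec
from gabapk.saem import SAEMSettings, fit_saem


@pytest.fixture(scope="module")
def calibrated_fit(truth_spec):
    """Data simulated from the final model, 'fitted' at the truth itself.

    Using the generating spec as the fitted model makes the residual
    calibration exact by construction, which is what the checks target.
    """
    cfg = CohortConfig(n_subjects=60, seed=19)
    designed = rich_design(generate_cohort(cfg))
    ds, _ = simulate_concentrations(designed, truth_spec, seed=23)
    fit = fit_saem(ds, truth_spec,
                   SAEMSettings(n_burnin=30, n_smooth=20, seed=1))
    fit.spec = truth_spec
    fit.ebes = None
    return fit, ds


class TestResiduals:
    def test_row_count_equals_observations(self, calibrated_fit):
        fit, ds = calibrated_fit
        table = residuals(fit, ds, n_sim=300, seed=2).table
        assert len(table) == ds.n_observations
        assert np.all(np.isfinite(table["iwres"]))

    def test_iwres_zero_when_observation_equals_prediction(self, truth_spec):
        spec = replace(truth_spec,
                       random_effects=RandomEffectsSpec(1e-4, 1e-4),
                       error=ErrorModelSpec(kind="constant", a=2.03))
        cfg = CohortConfig(n_subjects=5, seed=3)
        designed = rich_design(generate_cohort(cfg), sample_offsets=(3.0,))
        noise_free = replace(spec, error=ErrorModelSpec(kind="constant",
                                                        a=1e-12))
        ds, _ = simulate_concentrations(designed, noise_free, seed=4)
        fit = fit_saem(ds, spec, SAEMSettings(n_burnin=10, n_smooth=5, seed=5))
        fit.spec = spec
        fit.ebes = None
        table = residuals(fit, ds, n_sim=200, seed=6).table
        # observations equal the (typical) predictions, so IWRES ~ 0
        # (to the tolerance of the EBE optimiser)
        assert np.allclose(table["iwres"], 0.0, atol=1e-3)

    def test_iwres_unity_for_one_sigma_residual(self, truth_spec):
        # constant error a = 2.03 and y - f = 2.03 gives IWRES exactly 1
        spec = replace(truth_spec,
                       random_effects=RandomEffectsSpec(1e-4, 1e-4))
        cfg = CohortConfig(n_subjects=4, seed=7)
        designed = rich_design(generate_cohort(cfg), sample_offsets=(3.0,))
        noise_free = replace(spec, error=ErrorModelSpec(kind="constant",
                                                        a=1e-12))
        ds, _ = simulate_concentrations(designed, noise_free, seed=8)
        shifted = PKDataset(subjects=[
            replace(s, observations=[
                replace(o, concentration=o.concentration + 2.03)
                for o in s.observations
            ]) for s in ds.subjects
        ])
        fit = fit_saem(ds, spec, SAEMSettings(n_burnin=10, n_smooth=5, seed=9))
        fit.spec = spec
        fit.ebes = None
        table = residuals(fit, shifted, n_sim=200, seed=10).table
        assert np.allclose(table["iwres"], 1.0, atol=1e-3)

    def test_calibration_under_the_generating_model(self, calibrated_fit):
        fit, ds = calibrated_fit
        table = residuals(fit, ds, n_sim=500, seed=11).table
        assert abs(table["iwres"].mean()) < 0.1
        assert 0.85 < table["iwres"].std() < 1.15
        # PWRES observations within a subject share an eta, so the
        # effective sample size is the subject count, not the row count
        assert abs(table["pwres"].mean()) < 0.25
        assert 0.85 < table["pwres"].std() < 1.15


class TestVPC:
    def test_bands_nest_and_cover(self, calibrated_fit):
        fit, ds = calibrated_fit
        v = vpc(fit, ds, n_rep=300, bins=4, seed=12)
        assert np.all(v.simulated["p5"] <= v.simulated["p50"])
        assert np.all(v.simulated["p50"] <= v.simulated["p95"])
        # ~90% of observations inside the simulated 5-95 band
        y = np.array([o.concentration for s in ds.subjects
                      for o in s.observations])
        t = np.array([o.time for s in ds.subjects for o in s.observations])
        idx = np.clip(np.searchsorted(v.bin_edges, t, side="right") - 1,
                      0, len(v.bin_edges) - 2)
        inside = np.mean((y >= v.simulated["p5"].to_numpy()[idx])
                         & (y <= v.simulated["p95"].to_numpy()[idx]))
        assert 0.85 <= inside <= 0.97

    def test_degenerate_model_collapses_bands(self, truth_spec):
        spec = replace(truth_spec, covariate_effects=(),
                       random_effects=RandomEffectsSpec(1e-6, 1e-6),
                       error=ErrorModelSpec(kind="constant", a=1e-9))
        cfg = CohortConfig(n_subjects=30, seed=13)
        designed = rich_design(generate_cohort(cfg), sample_offsets=(3.0,))
        ds, _ = simulate_concentrations(designed, spec, seed=14)
        fit = fit_saem(ds, spec, SAEMSettings(n_burnin=10, n_smooth=5, seed=15))
        fit.spec = spec
        v = vpc(fit, ds, n_rep=150, bins=2, seed=16)
        assert np.allclose(v.simulated["p5"], v.simulated["p95"], atol=1e-6)

    def test_analytic_quantiles_for_zero_omega_constant_error(self,
                                                              truth_spec):
        # omega = 0, constant a: each bin's percentiles are f +/- 1.645 a
        # (no covariate effect, so every subject shares the same f)
        a = 2.03
        spec = replace(truth_spec, covariate_effects=(),
                       random_effects=RandomEffectsSpec(1e-6, 1e-6))
        cfg = CohortConfig(n_subjects=400, seed=17, dose_menu={300: 1.0},
                           intervals=(8,), interval_weights=(1.0,))
        designed = rich_design(generate_cohort(cfg), sample_offsets=(3.0,))
        ds, _ = simulate_concentrations(designed, spec, seed=18)
        fit = fit_saem(ds, spec, SAEMSettings(n_burnin=10, n_smooth=5, seed=19))
        fit.spec = spec
        v = vpc(fit, ds, n_rep=400, bins=1, seed=20)
        f = float(np.median([o.concentration for s in ds.subjects
                             for o in s.observations]))
        # typical prediction: all subjects share design and (eta=0) parameters
        from gabapk.population import individual_parameters
        from gabapk.structural import concentration_first_order
        p = individual_parameters(spec, ds.subjects[0].covariates)
        f_typ = concentration_first_order(
            ds.subjects[0].observations[0].time, ds.subjects[0].doses, p)
        assert v.simulated["p95"].iloc[0] == pytest.approx(
            f_typ + 1.645 * a, abs=0.25)
        assert v.simulated["p5"].iloc[0] == pytest.approx(
            f_typ - 1.645 * a, abs=0.25)

    def test_bands_widen_with_variability(self, truth_spec):
        cfg = CohortConfig(n_subjects=50, seed=21)
        designed = rich_design(generate_cohort(cfg))
        ds, _ = simulate_concentrations(designed, truth_spec, seed=22)
        fit = fit_saem(ds, truth_spec,
                       SAEMSettings(n_burnin=10, n_smooth=5, seed=23))
        narrow = replace(truth_spec,
                         random_effects=RandomEffectsSpec(0.2, 0.1),
                         error=ErrorModelSpec(kind="constant", a=0.5))
        fit.spec = narrow
        v_narrow = vpc(fit, ds, n_rep=200, bins=3, seed=24)
        fit.spec = truth_spec
        fit.ebes = None
        v_wide = vpc(fit, ds, n_rep=200, bins=3, seed=24)
        width_n = (v_narrow.simulated["p95"] - v_narrow.simulated["p5"]).mean()
        width_w = (v_wide.simulated["p95"] - v_wide.simulated["p5"]).mean()
        assert width_w > width_n


class TestBootstrap:
    def test_same_seed_identical_results(self, truth_spec):
        cfg = CohortConfig(n_subjects=25, seed=25)
        designed = rich_design(generate_cohort(cfg))
        ds, _ = simulate_concentrations(designed, truth_spec, seed=26)
        settings = SAEMSettings(n_burnin=60, n_smooth=40)
        b1 = bootstrap(ds, truth_spec, n_rep=4, seed=3, settings=settings)
        b2 = bootstrap(ds, truth_spec, n_rep=4, seed=3, settings=settings)
        assert b1.summary.equals(b2.summary)

    def test_duplicated_subject_dataset_centres_on_point_estimate(self,
                                                                  truth_spec):
        # a cohort of identical subjects makes resampling a no-op, so the
        # bootstrap medians coincide with the point estimates
        cfg = CohortConfig(n_subjects=1, seed=27)
        # dense low-noise profile so that V and Cl are sharply identified
        # from the single (duplicated) subject
        base = rich_design(generate_cohort(cfg),
                           sample_offsets=(0.5, 1, 2, 3, 5, 8))
        low_noise = replace(truth_spec,
                            error=ErrorModelSpec(kind="constant", a=0.3))
        ds1, _ = simulate_concentrations(base, low_noise, seed=28)
        proto = ds1.subjects[0]
        subjects = [replace(proto, id=f"S{i}") for i in range(12)]
        ds = PKDataset(subjects=subjects)
        # a covariate effect is unidentifiable from a single SCr value,
        # so the duplicated cohort is fitted without one
        spec = replace(truth_spec, covariate_effects=())
        settings = SAEMSettings(n_burnin=80, n_smooth=60)
        fit = fit_saem(ds, spec, replace(settings, seed=0))
        b = bootstrap(ds, spec, n_rep=6, seed=4, settings=settings)
        for k in ("v_pop", "cl_pop", "a"):
            assert b.summary.loc[k, "median"] == pytest.approx(
                fit.estimates[k], rel=0.15)

    def test_interval_contains_median(self, truth_spec):
        cfg = CohortConfig(n_subjects=25, seed=29)
        designed = rich_design(generate_cohort(cfg))
        ds, _ = simulate_concentrations(designed, truth_spec, seed=30)
        b = bootstrap(ds, truth_spec, n_rep=6, seed=5,
                      settings=SAEMSettings(n_burnin=60, n_smooth=40))
        assert (b.summary["ci_low"] <= b.summary["median"]).all()
        assert (b.summary["median"] <= b.summary["ci_high"]).all()
        assert b.n_converged == 6
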