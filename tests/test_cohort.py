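"""Synthetic cohort generator: distributions, design, reproducibility."""

import numpy as np
import pytest
from dataclasses import replace

from gabapk.cohort import (
    CohortConfig, default_truth_spec, generate_cohort, generate_design,
    rich_design, simulate_concentrations, simulate_dataset,
)
from gabapk.population import ErrorModelSpec, RandomEffectsSpec
from gabapk.structural import concentration_first_order


class TestCohort:
    def test_default_cohort_matches_study_demographics(self):
        cfg = CohortConfig(n_subjects=82, seed=1)
        subjects = generate_cohort(cfg)
        ages = np.array([s.covariates.age for s in subjects])
        assert abs(ages.mean() - 65.7) < 4.0
        assert ages.min() >= 22.0 and ages.max() <= 93.0
        scr = np.array([s.covariates.scr for s in subjects])
        assert scr.min() >= 0.4 and scr.max() <= 3.8

    def test_large_cohort_diabetes_fraction(self):
        subjects = generate_cohort(CohortConfig(n_subjects=10000, seed=2))
        frac = np.mean([s.covariates.diabetes for s in subjects])
        assert abs(frac - 0.317) < 0.02

    def test_determinism(self):
        a = generate_cohort(CohortConfig(n_subjects=50, seed=9))
        b = generate_cohort(CohortConfig(n_subjects=50, seed=9))
        assert all(x.covariates == y.covariates for x, y in zip(a, b))

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(age_range=(90.0, 20.0))


class TestDesign:
    def test_observation_counts_emulate_tdm_sparsity(self):
        cfg = CohortConfig(n_subjects=82, seed=3)
        designed = generate_design(generate_cohort(cfg), cfg)
        n_obs = sum(len(s.observations) for s in designed)
        assert 82 <= n_obs <= 164
        assert 1.0 <= n_obs / 82 <= 1.3  # mean ~1.15 samples/subject

    def test_dose_median_is_300(self):
        cfg = CohortConfig(n_subjects=10000, seed=4)
        designed = generate_design(generate_cohort(cfg), cfg)
        amounts = np.array([s.doses[0].amount for s in designed])
        assert np.median(amounts) == 300.0
        assert amounts.min() >= 100.0 and amounts.max() <= 1200.0

    def test_samples_strictly_after_first_dose(self):
        cfg = CohortConfig(n_subjects=200, seed=5)
        designed = generate_design(generate_cohort(cfg), cfg)
        for s in designed:
            for o in s.observations:
                assert o.time > s.doses[0].time


class TestSimulation:
    def test_noise_free_limit_equals_typical_curve(self, truth_spec):
        spec = replace(truth_spec,
                       random_effects=RandomEffectsSpec(0.0, 0.0),
                       error=ErrorModelSpec(kind="constant", a=1e-12))
        cfg = CohortConfig(n_subjects=5, seed=6)
        designed = generate_design(generate_cohort(cfg), cfg)
        ds, truth = simulate_concentrations(designed, spec, seed=8)
        from gabapk.population import individual_parameters
        for s in ds.subjects:
            p = individual_parameters(spec, s.covariates)
            t = np.array([o.time for o in s.observations])
            expected = np.atleast_1d(concentration_first_order(t, s.doses, p))
            got = np.array([o.concentration for o in s.observations])
            assert np.allclose(got, expected, atol=1e-9)

    def test_full_reproducibility(self):
        a, ta = simulate_dataset(CohortConfig(n_subjects=30, seed=12))
        b, tb = simulate_dataset(CohortConfig(n_subjects=30, seed=12))
        ya = [o.concentration for s in a.subjects for o in s.observations]
        yb = [o.concentration for s in b.subjects for o in s.observations]
        assert ya == yb
        for p in ta.etas:
            assert np.array_equal(ta.etas[p], tb.etas[p])

    def test_reference_range_contains_bulk_of_values(self):
        ds, _ = simulate_dataset(CohortConfig(n_subjects=2000, seed=13))
        y = np.array([o.concentration for s in ds.subjects
                      for o in s.observations])
        # clinical reference range 2.0-20.0 ug/mL should hold the bulk
        assert np.mean((y >= 2.0) & (y <= 20.0)) >= 0.60

    def test_steady_state_mean_matches_population_oracle(self, truth_spec):
        # Monte-Carlo mean of simulated subjects (300 mg q8h steady state,
        # sampled 3 h post-dose) vs the population mean computed by
        # Gauss-Hermite integration over the (V, Cl) random effects
        cfg = CohortConfig(n_subjects=4000, seed=14)
        shells = generate_cohort(cfg)
        designed = rich_design(shells, sample_offsets=(3.0,))
        ds, _ = simulate_concentrations(designed, truth_spec, seed=15)
        y = np.array([s.observations[0].concentration for s in ds.subjects])

        from gabapk.structural import predict_first_order
        import numpy.polynomial.hermite as H
        scr = np.array([s.covariates.scr for s in designed])
        cl_typ = 5.73 * (scr / 1.3) ** -0.89
        t_obs = np.full(scr.size, designed[0].observations[0].time)
        dt = np.array([d.time for d in designed[0].doses])
        da = np.array([d.amount for d in designed[0].doses])
        dt2 = np.broadcast_to(dt, (scr.size, dt.size))
        da2 = np.broadcast_to(da, (scr.size, da.size))
        z, w = H.hermgauss(24)
        oracle_terms = np.zeros(scr.size)
        for zi, wi in zip(z, w):
            v_i = 44.61 * np.exp(np.sqrt(2) * 0.77 * zi)
            for zj, wj in zip(z, w):
                cl_ij = cl_typ * np.exp(np.sqrt(2) * 0.28 * zj)
                c = predict_first_order(
                    t_obs, dt2, da2, np.full(scr.size, v_i), cl_ij,
                    0.778, 0.0)
                oracle_terms += wi * wj / np.pi * c
        oracle = float(oracle_terms.mean())
        assert abs(y.mean() - oracle) / oracle < 0.10
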