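"""Shared fixtures: small synthetic cohorts and an independent ODE oracle."""

import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gabapk.cohort import (
    CohortConfig, default_truth_spec, generate_cohort, generate_design,
    rich_design, simulate_concentrations,
)
from gabapk.saem import SAEMSettings
from gabapk.structural import bioavailability

warnings.filterwarnings(
    "ignore", message="height below 60 inches.*", category=UserWarning,
)


@pytest.fixture(scope="session")
def truth_spec():
    """The published final model, used as generating truth."""
    return default_truth_spec()


@pytest.fixture(scope="session")
def fast_settings():
    return SAEMSettings(n_burnin=150, n_smooth=100, seed=0)


@pytest.fixture(scope="session")
def small_tdm_dataset(truth_spec):
    """A 20-subject sparse TDM dataset simulated from the final model."""
    cfg = CohortConfig(n_subjects=20, seed=11)
    shells = generate_design(generate_cohort(cfg), cfg)
    ds, truth = simulate_concentrations(shells, truth_spec, seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def rich_dataset(truth_spec):
    """A 40-subject rich-design dataset (q8h to steady state, 4 samples)."""
    cfg = CohortConfig(n_subjects=40, seed=5)
    designed = rich_design(generate_cohort(cfg))
    ds, truth = simulate_concentrations(designed, truth_spec, seed=17)
    return ds, truth


def ode_concentration(t_eval, doses, params):
    """Independent numeric oracle for the oral one-compartment model.

    Integrates gut/central amounts with bolus-to-gut events at each dose
    (amount scaled by the saturable bioavailability), rtol 1e-11.
    """
    ke = params.cl / params.v

    def rhs(t, y):
        return [-params.ka * y[0], params.ka * y[0] - ke * y[1]]

    events = {}
    for d in doses:
        events[d.time + params.tlag] = (
            events.get(d.time + params.tlag, 0.0)
            + bioavailability(d.amount, params.dmax, params.d50) * d.amount
        )
    t_eval = list(np.atleast_1d(t_eval).astype(float))
    checkpoints = sorted(set(list(events) + t_eval))
    y = [0.0, 0.0]
    t_cur = 0.0
    out = {}
    for tp in checkpoints:
        if tp > t_cur:
            sol = solve_ivp(rhs, (t_cur, tp), y, rtol=1e-11, atol=1e-13)
            y = list(sol.y[:, -1])
            t_cur = tp
        if tp in events:
            y[0] += events[tp]
        if tp in t_eval:
            out[tp] = y[1] / params.v
    return np.array([out[t] for t in t_eval])
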