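"""Structural PK model against hand values and an independent ODE oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from gabapk.dataset import DoseEvent
from gabapk.structural import (
    StructuralParams, bioavailability, concentration_first_order,
    concentration_steady_state, concentration_transit,
)

from conftest import ode_concentration

FINAL = StructuralParams(v=44.61, cl=5.73, ka=0.778)


class TestBioavailability:
    def test_saturable_fraction_values(self):
        assert bioavailability(300) == pytest.approx(823 / 1420)
        assert bioavailability(0) == pytest.approx(823 / 1120)
        # half-saturation symmetry: F(D50) is exactly half the zero-dose limit
        assert bioavailability(1120) == pytest.approx(0.5 * 823 / 1120)

    def test_strictly_decreasing_and_bounded(self):
        doses = np.linspace(0, 2400, 49)
        f = bioavailability(doses)
        assert np.all(np.diff(f) < 0)
        assert np.all(f <= 823 / 1120)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            bioavailability(-1.0)


class TestFirstOrder:
    def test_zero_before_absorption(self):
        assert concentration_first_order(0.0, [DoseEvent(0, 300)], FINAL) == 0.0

    def test_single_dose_hand_value(self):
        c = concentration_first_order(3.0, [DoseEvent(0, 300)], FINAL)
        assert c == pytest.approx(2.723, abs=5e-4)

    def test_two_dose_superposition_hand_value(self):
        doses = [DoseEvent(0, 300), DoseEvent(8, 300)]
        c = concentration_first_order(11.0, doses, FINAL)
        assert c == pytest.approx(3.859, abs=5e-4)
        # equals the sum of the single-dose profile at 11 h and 3 h
        single = concentration_first_order(
            np.array([11.0, 3.0]), [DoseEvent(0, 300)], FINAL)
        assert c == pytest.approx(single.sum())

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = StructuralParams(
                v=rng.uniform(20, 120), cl=rng.uniform(2, 15),
                ka=rng.uniform(0.2, 2.5), tlag=rng.choice([0.0, 0.31]),
            )
            n_dose = rng.integers(1, 5)
            doses = [DoseEvent(time=8.0 * i, amount=float(rng.choice([100, 300, 600, 1200])))
                     for i in range(n_dose)]
            t = np.sort(rng.uniform(0.5, 40.0, size=4))
            closed = concentration_first_order(t, doses, p)
            oracle = ode_concentration(t, doses, p)
            mask = oracle > 1e-6
            assert np.allclose(closed[mask], oracle[mask], rtol=1e-8)

    def test_ka_equals_ke_limit_is_continuous(self):
        # Cl/V chosen so that ke == ka triggers the analytic limit branch
        v = 40.0
        degenerate = StructuralParams(v=v, cl=0.778 * v, ka=0.778)
        near = StructuralParams(v=v, cl=0.778 * v * (1 + 1e-6), ka=0.778)
        t = np.array([1.0, 4.0, 12.0])
        d = [DoseEvent(0, 300)]
        assert np.allclose(
            concentration_first_order(t, d, degenerate),
            concentration_first_order(t, d, near), rtol=1e-4)

    def test_increasing_clearance_lowers_post_peak_concentration(self):
        t = np.array([6.0, 12.0, 24.0])  # all past the absorption peak
        d = [DoseEvent(0, 300)]
        lo = concentration_first_order(t, d, StructuralParams(v=44.61, cl=4.0, ka=0.778))
        hi = concentration_first_order(t, d, StructuralParams(v=44.61, cl=8.0, ka=0.778))
        assert np.all(hi < lo)

    def test_dose_nonproportionality(self):
        # saturable F makes the 4x dose give < 4x the concentration everywhere
        t = np.linspace(0.25, 36, 100)
        d300 = concentration_first_order(t, [DoseEvent(0, 300)], FINAL)
        d1200 = concentration_first_order(t, [DoseEvent(0, 1200)], FINAL)
        assert np.all(d1200 / d300 < 4.0)

    def test_steady_state_matches_long_superposition(self):
        tau = 8.0
        doses = [DoseEvent(8.0 * i, 300.0) for i in range(150)]
        t_last = doses[-1].time
        offsets = np.array([1.0, 3.0, 6.0, 7.9])
        ss = concentration_steady_state(offsets, 300.0, tau, FINAL)
        sup = concentration_first_order(t_last + offsets, doses, FINAL)
        assert np.allclose(ss, sup, rtol=1e-6)


class TestTransit:
    PT = StructuralParams(v=44.61, cl=5.73, ka=0.778, n_transit=3, ktr=1.5)

    def test_zero_at_time_zero(self):
        assert concentration_transit(0.0, [DoseEvent(0, 300)], self.PT) == 0.0

    def test_matches_ode_integration(self):
        from scipy.integrate import solve_ivp
        p = self.PT
        n = p.n_transit

        def rhs(t, y):
            dy = np.zeros(n + 2)
            dy[0] = -p.ktr * y[0]
            for j in range(1, n):
                dy[j] = p.ktr * (y[j - 1] - y[j])
            dy[n] = p.ktr * y[n - 1] - p.ka * y[n]
            dy[n + 1] = p.ka * y[n] - p.ke * y[n + 1]
            return dy

        y0 = np.zeros(n + 2)
        y0[0] = bioavailability(300) * 300
        for t in (0.5, 2.0, 5.0, 12.0):
            sol = solve_ivp(rhs, (0, t), y0, rtol=1e-11, atol=1e-13)
            expected = sol.y[n + 1, -1] / p.v
            assert concentration_transit(t, [DoseEvent(0, 300)], p) == \
                pytest.approx(expected, rel=1e-8)

    def test_mass_balance_with_coincident_rates(self):
        # n=1, ktr = ka: total eliminated drug equals the absorbed dose F*D
        p = StructuralParams(v=44.61, cl=5.73, ka=0.778, n_transit=1, ktr=0.778)
        ke_v = p.cl  # ke * V = Cl

        total, _ = quad(
            lambda t: ke_v * concentration_transit(t, [DoseEvent(0, 300)], p),
            0, 400, limit=400,
        )
        assert total == pytest.approx(bioavailability(300) * 300, rel=1e-6)

    def test_fast_transit_approaches_first_order(self):
        p = StructuralParams(v=44.61, cl=5.73, ka=0.778, n_transit=1,
                             ktr=300 * 0.778)
        t = np.linspace(0.25, 24, 96)
        d = [DoseEvent(0, 300)]
        ref = concentration_first_order(t, d, FINAL)
        diff = np.max(np.abs(concentration_transit(t, d, p) - ref))
        assert diff / ref.max() < 0.01

    def test_zero_transit_convention_reduces_to_first_order(self):
        p0 = StructuralParams(v=44.61, cl=5.73, ka=0.778, n_transit=0)
        t = np.array([1.0, 5.0, 10.0])
        d = [DoseEvent(0, 300)]
        assert np.allclose(concentration_transit(t, d, p0),
                           concentration_first_order(t, d, FINAL))
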