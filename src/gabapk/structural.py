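"""Structural PK models for oral gabapentin.

One-compartment disposition with first-order elimination and saturable,
dose-dependent oral bioavailability

    F(Dose) = Dmax / (D50 + Dose)

with Dmax = 823 and D50 = 1120 fixed to literature values.  Absorption is
either first order (optionally lagged) or a transit-compartment chain.
Concentrations superpose over the recorded dose history; amounts in mg and
volumes in L make the output mg/L, numerically identical to ug/mL.

All evaluators are vectorised over observation times and (broadcastable)
parameter arrays, which is what makes SAEM fitting cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Optional, Sequence

import numpy as np

from .dataset import DoseEvent

__all__ = [
    "StructuralParams",
    "DMAX_DEFAULT",
    "D50_DEFAULT",
    "KA_FIXED",
    "TLAG_FIXED",
    "bioavailability",
    "concentration_first_order",
    "concentration_transit",
    "concentration_steady_state",
    "predict_first_order",
    "predict_transit",
]

DMAX_DEFAULT = 823.0  # mg/day; maximal absorption parameter of the saturable F
D50_DEFAULT = 1120.0  # mg/day; dose at 50% saturation of absorption
KA_FIXED = 0.778  # 1/h; literature absorption rate constant, fixed
TLAG_FIXED = 0.31  # h; literature lag time for the lagged candidate model

_KA_KE_RTOL = 1e-8  # switch to the ka=ke analytic limit below this


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters of the oral one-compartment model."""

    v: float  # volume of distribution, L
    cl: float  # clearance, L/h
    ka: float = KA_FIXED  # absorption rate constant, 1/h
    tlag: float = 0.0  # absorption lag time, h
    dmax: float = DMAX_DEFAULT
    d50: float = D50_DEFAULT
    n_transit: int = 0
    ktr: Optional[float] = None  # transit rate, 1/h (used iff n_transit > 0)

    def __post_init__(self):
        if not (self.v > 0 and self.cl > 0 and self.ka > 0):
            raise ValueError("V, Cl and ka must be strictly positive")
        if self.tlag < 0:
            raise ValueError("Tlag must be >= 0")
        if not (self.dmax > 0 and self.d50 > 0):
            raise ValueError("Dmax and D50 must be strictly positive")
        if self.n_transit < 0:
            raise ValueError("n_transit must be >= 0")
        if self.n_transit > 0 and not (self.ktr and self.ktr > 0):
            raise ValueError("ktr must be > 0 when n_transit > 0")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant Cl/V, 1/h."""
        return self.cl / self.v


def bioavailability(dose, dmax: float = DMAX_DEFAULT, d50: float = D50_DEFAULT):
    """Saturable oral bioavailability F = Dmax / (D50 + Dose).

    Strictly decreasing in dose and bounded above by the zero-dose limit
    Dmax/D50.  `dose` may be a scalar or array (mg).
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = dmax / (d50 + dose)
    return float(out) if out.ndim == 0 else out


def _one_dose_first_order(tau, fd, v, ka, ke):
    """Post-dose concentration for one absorbed amount fd = F*D at tau >= 0.

    Handles the ka ~= ke degeneracy with the analytic limit
    fd*ka*tau*exp(-ka*tau)/v to avoid catastrophic cancellation.
    """
    tau = np.maximum(tau, 0.0)
    active = tau > 0
    diff = ka - ke
    degenerate = np.abs(diff) < _KA_KE_RTOL * np.abs(ka)
    safe_diff = np.where(degenerate, 1.0, diff)
    # extreme sampled parameters (MH proposals) can overflow the exp; the
    # resulting inf/nan lands in the unselected where-branch
    with np.errstate(over="ignore", invalid="ignore"):
        general = fd * ka / (v * safe_diff) * (np.exp(-ke * tau)
                                               - np.exp(-ka * tau))
        limit = fd * ka * tau * np.exp(-ka * tau) / v
        return np.where(active, np.where(degenerate, limit, general), 0.0)


def predict_first_order(t, dose_times, dose_amounts, v, cl, ka, tlag,
                        dmax: float = DMAX_DEFAULT, d50: float = D50_DEFAULT):
    """Vectorised first-order model over padded dose arrays.

    Parameters
    ----------
    t : (n,) observation times, h.
    dose_times, dose_amounts : (n, m) per-observation dose history, padded
        with zero amounts (a zero amount contributes nothing).
    v, cl, ka, tlag : scalars or (n,) arrays.

    Returns
    -------
    (n,) concentrations, ug/mL.
    """
    t = np.asarray(t, dtype=float)
    dose_times = np.atleast_2d(np.asarray(dose_times, dtype=float))
    dose_amounts = np.atleast_2d(np.asarray(dose_amounts, dtype=float))
    v = np.asarray(v, dtype=float)[..., None]
    ka = np.asarray(ka, dtype=float)[..., None]
    ke = np.asarray(cl, dtype=float)[..., None] / v
    tlag = np.asarray(tlag, dtype=float)[..., None]
    tau = t[..., None] - dose_times - tlag
    fd = bioavailability(dose_amounts, dmax, d50) * dose_amounts
    terms = _one_dose_first_order(tau, fd, v, ka, ke)
    return terms.sum(axis=-1)


def concentration_first_order(t, doses: Sequence[DoseEvent],
                              params: StructuralParams):
    """Concentration-time profile by superposition over the dose history.

    ``t`` may be a scalar or array of times (h since the first dose).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    dt = np.array([d.time for d in doses], dtype=float)
    da = np.array([d.amount for d in doses], dtype=float)
    out = predict_first_order(
        t_arr, np.broadcast_to(dt, (t_arr.size, dt.size)),
        np.broadcast_to(da, (t_arr.size, da.size)),
        params.v, params.cl, params.ka, params.tlag, params.dmax, params.d50,
    )
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def concentration_steady_state(t_after_dose, dose: float, tau_interval: float,
                               params: StructuralParams):
    """Steady-state profile of a regular regimen (dose every ``tau_interval`` h).

    Closed-form geometric accumulation of the first-order model; valid for
    0 <= t_after_dose (times beyond one interval wrap implicitly via the
    exponential terms).
    """
    if tau_interval <= 0:
        raise ValueError("dosing interval must be positive")
    t = np.asarray(t_after_dose, dtype=float) - params.tlag
    ke, ka, v = params.ke, params.ka, params.v
    fd = bioavailability(dose, params.dmax, params.d50) * dose
    if abs(ka - ke) < _KA_KE_RTOL * ka:
        raise NotImplementedError("steady-state ka=ke limit not supported")
    acc_ke = np.exp(-ke * t) / (1.0 - np.exp(-ke * tau_interval))
    acc_ka = np.exp(-ka * t) / (1.0 - np.exp(-ka * tau_interval))
    out = fd * ka / (v * (ka - ke)) * (acc_ke - acc_ka)
    return float(out) if out.ndim == 0 else out


def _separate(a: float, b: float, rel: float = 1e-7) -> float:
    """Nudge b away from a when nearly coincident (keeps partial fractions stable)."""
    scale = max(abs(a), abs(b), 1e-12)
    if abs(a - b) < rel * scale:
        return b + rel * scale
    return b


def _transit_single_dose(tau, fd, v, ka, ke, n, ktr):
    """Central concentration after one dose through an n-compartment transit chain.

    Chain: dose -> n serial transit compartments (rate ktr each) ->
    absorption compartment (emptying at ka) -> central (elimination ke).
    Exact inverse Laplace transform with the repeated transit pole of
    order n treated analytically; the simple poles ka, ke are nudged apart
    from ktr (and each other) by 1e-7 relative when coincident.
    """
    tau = np.maximum(np.asarray(tau, dtype=float), 0.0)
    a = float(ktr)
    b = _separate(a, float(ka))
    c = _separate(a, _separate(b, float(ke)))
    # partial fractions of 1/((s+a)^n (s+b)(s+c))
    Bcoef = 1.0 / ((a - b) ** n * (c - b))
    Ccoef = 1.0 / ((a - c) ** n * (b - c))
    out = Bcoef * np.exp(-b * tau) + Ccoef * np.exp(-c * tau)
    for i in range(n):  # A_{n-i} coefficients
        j = n - i
        Aj = ((-1.0) ** i / (c - b)) * (
            (b - a) ** -(i + 1) - (c - a) ** -(i + 1)
        )
        out = out + Aj * tau ** (j - 1) * np.exp(-a * tau) / factorial(j - 1)
    gain = fd * a ** n * b / v
    return np.where(tau > 0, gain * out, 0.0)


def predict_transit(t, dose_times, dose_amounts, v, cl, ka, tlag, n_transit,
                    ktr, dmax: float = DMAX_DEFAULT, d50: float = D50_DEFAULT):
    """Vectorised transit-absorption model over padded dose arrays.

    Shapes follow :func:`predict_first_order`; ``v``/``cl`` may vary per
    observation but ``ka``, ``ktr``, ``n_transit`` are scalars.
    """
    if n_transit < 1:
        return predict_first_order(t, dose_times, dose_amounts, v, cl, ka,
                                   tlag, dmax, d50)
    t = np.asarray(t, dtype=float)
    dose_times = np.atleast_2d(np.asarray(dose_times, dtype=float))
    dose_amounts = np.atleast_2d(np.asarray(dose_amounts, dtype=float))
    v_arr = np.asarray(v, dtype=float)[..., None]
    ke_arr = (np.asarray(cl, dtype=float) / np.asarray(v, dtype=float))[..., None]
    tau = t[..., None] - dose_times - tlag
    fd = bioavailability(dose_amounts, dmax, d50) * dose_amounts
    # ke varies per observation -> loop-free evaluation requires the partial
    # fractions per element; vectorise by broadcasting the coefficient algebra
    a = float(ktr)
    b = float(ka)
    scale = max(a, b)
    if abs(a - b) < 1e-7 * scale:
        b = b + 1e-7 * scale
    c = np.where(np.abs(ke_arr - a) < 1e-7 * np.maximum(a, ke_arr),
                 ke_arr + 1e-7 * np.maximum(a, ke_arr), ke_arr)
    c = np.where(np.abs(c - b) < 1e-7 * np.maximum(b, c),
                 c + 1e-7 * np.maximum(b, c), c)
    tau_pos = np.maximum(tau, 0.0)
    Bcoef = 1.0 / ((a - b) ** n_transit * (c - b))
    Ccoef = 1.0 / ((a - c) ** n_transit * (b - c))
    out = Bcoef * np.exp(-b * tau_pos) + Ccoef * np.exp(-c * tau_pos)
    for i in range(n_transit):
        j = n_transit - i
        Aj = ((-1.0) ** i / (c - b)) * (
            (b - a) ** -(i + 1) - (c - a) ** -(i + 1)
        )
        out = out + Aj * tau_pos ** (j - 1) * np.exp(-a * tau_pos) / factorial(j - 1)
    gain = fd * a ** n_transit * b / v_arr
    terms = np.where(tau > 0, gain * out, 0.0)
    return terms.sum(axis=-1)


def concentration_transit(t, doses: Sequence[DoseEvent], params: StructuralParams):
    """Transit-chain concentration profile by superposition over doses."""
    if params.n_transit < 1:
        return concentration_first_order(t, doses, params)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    dt = np.array([d.time for d in doses], dtype=float)
    da = np.array([d.amount for d in doses], dtype=float)
    out = predict_transit(
        t_arr, np.broadcast_to(dt, (t_arr.size, dt.size)),
        np.broadcast_to(da, (t_arr.size, da.size)),
        np.full(t_arr.size, params.v), np.full(t_arr.size, params.cl),
        params.ka, params.tlag, params.n_transit, params.ktr,
        params.dmax, params.d50,
    )
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
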