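"""Population layer: fixed effects, covariate effects, random effects, residual error.

Individual parameters are log-normal around the typical value with
power-law (log-linear) covariate effects:

    log psi_i = log psi_pop + sum_c beta_c * x_ci + eta_i,

where x_ci = log(cov_i / ref) for continuous covariates (centered at a
reference value, by default the cohort mean) and a 0/1 indicator for
categorical covariates.  eta_i ~ N(0, omega^2), independently per
parameter; in the final gabapentin model only V and Cl carry random
effects.  The residual model is Gaussian with SD given by a constant (a),
proportional (b*f) or combined (sqrt(a^2 + (b*f)^2)) rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .dataset import CovariateRecord, CONTINUOUS_COVARIATES
from .structural import (
    D50_DEFAULT, DMAX_DEFAULT, KA_FIXED, StructuralParams,
)

__all__ = [
    "FixedEffects",
    "CovariateEffect",
    "RandomEffectsSpec",
    "ErrorModelSpec",
    "PopulationModelSpec",
    "SCR_REF_DEFAULT",
    "individual_parameters",
    "residual_sd",
    "observation_loglik",
]

SCR_REF_DEFAULT = 1.3  # mg/dL; cohort mean serum creatinine used for centering

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FixedEffects:
    """Typical-subject (population) structural parameters."""

    v_pop: float = 44.61  # L
    cl_pop: float = 5.73  # L/h
    ka_pop: float = KA_FIXED  # 1/h, fixed in the final model
    tlag_pop: float = 0.0  # h

    def __post_init__(self):
        if not (self.v_pop > 0 and self.cl_pop > 0 and self.ka_pop > 0):
            raise ValueError("population parameters must be strictly positive")
        if self.tlag_pop < 0:
            raise ValueError("tlag_pop must be >= 0")


@dataclass(frozen=True)
class CovariateEffect:
    """A power-law covariate effect beta on one structural parameter.

    For continuous covariates the design value is log(cov/reference); for
    categorical covariates it is the 0/1 indicator and ``reference`` is
    ignored.
    """

    parameter: str  # 'v', 'cl', 'ka' or 'tlag'
    covariate: str  # column-style name, e.g. 'SCR', 'WT', 'DM'
    beta: float = 0.0
    reference: float = 1.0

    def __post_init__(self):
        if self.parameter not in ("v", "cl", "ka", "tlag"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.is_continuous and not self.reference > 0:
            raise ValueError("reference must be > 0 for continuous covariates")

    @property
    def is_continuous(self) -> bool:
        return self.covariate.upper() in CONTINUOUS_COVARIATES

    def design_value(self, cov: CovariateRecord) -> float:
        x = cov.value(self.covariate)
        if self.is_continuous:
            if x <= 0:
                raise ValueError(
                    f"covariate {self.covariate} must be > 0 for log transform"
                )
            return math.log(x / self.reference)
        return x


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Standard deviations of the log-scale random effects (0 = none)."""

    omega_v: float = 0.77
    omega_cl: float = 0.28

    def __post_init__(self):
        if self.omega_v < 0 or self.omega_cl < 0:
            raise ValueError("omegas must be >= 0")

    def omega(self, parameter: str) -> float:
        return {"v": self.omega_v, "cl": self.omega_cl}.get(parameter, 0.0)


@dataclass(frozen=True)
class ErrorModelSpec:
    """Residual-error model: constant, proportional or combined."""

    kind: str = "constant"
    a: float = 2.03  # ug/mL
    b: float = 0.0  # dimensionless

    def __post_init__(self):
        if self.kind not in ("constant", "proportional", "combined"):
            raise ValueError(f"unknown error model {self.kind!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError("error parameters must be >= 0")
        if self.a == 0 and self.b == 0:
            raise ValueError("error parameters cannot both be 0")


@dataclass(frozen=True)
class PopulationModelSpec:
    """Complete description of the statistical popPK model."""

    fixed: FixedEffects = field(default_factory=FixedEffects)
    covariate_effects: Sequence[CovariateEffect] = ()
    random_effects: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    error: ErrorModelSpec = field(default_factory=ErrorModelSpec)
    structural: str = "first_order"  # 'first_order' | 'first_order_lag' | 'transit'
    bioavailability: str = "saturable"  # 'saturable' (F = Dmax/(D50+Dose)) | 'constant'
    dmax: float = DMAX_DEFAULT
    d50: float = D50_DEFAULT
    n_transit: int = 0
    ktr: Optional[float] = None
    #: names of fixed (not estimated) population parameters
    fixed_parameters: Sequence[str] = ("ka", "tlag")

    def __post_init__(self):
        if self.structural not in ("first_order", "first_order_lag", "transit"):
            raise ValueError(f"unknown structural model {self.structural!r}")
        if self.bioavailability not in ("saturable", "constant"):
            raise ValueError(
                f"unknown bioavailability model {self.bioavailability!r}"
            )
        if self.structural == "transit" and self.n_transit < 1:
            raise ValueError("transit structural model needs n_transit >= 1")

    def effects_on(self, parameter: str) -> List[CovariateEffect]:
        return [e for e in self.covariate_effects if e.parameter == parameter]

    @property
    def random_parameters(self) -> List[str]:
        """Parameters carrying a random effect, in canonical order."""
        out = []
        if self.random_effects.omega_v > 0:
            out.append("v")
        if self.random_effects.omega_cl > 0:
            out.append("cl")
        return out

    def to_dict(self) -> Dict:
        """YAML-friendly nested-dict serialisation."""
        return {
            "fixed_effects": {
                "v_pop": self.fixed.v_pop, "cl_pop": self.fixed.cl_pop,
                "ka_pop": self.fixed.ka_pop, "tlag_pop": self.fixed.tlag_pop,
            },
            "covariate_effects": [
                {"parameter": e.parameter, "covariate": e.covariate,
                 "beta": e.beta, "reference": e.reference}
                for e in self.covariate_effects
            ],
            "random_effects": {
                "omega_v": self.random_effects.omega_v,
                "omega_cl": self.random_effects.omega_cl,
            },
            "error_model": {"kind": self.error.kind, "a": self.error.a,
                            "b": self.error.b},
            "structural": {
                "model": self.structural,
                "bioavailability": self.bioavailability,
                "dmax": self.dmax, "d50": self.d50,
                "n_transit": self.n_transit, "ktr": self.ktr,
                "fixed_parameters": list(self.fixed_parameters),
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModelSpec":
        fx = d.get("fixed_effects", {})
        re_ = d.get("random_effects", {})
        em = d.get("error_model", {})
        st = d.get("structural", {})
        return cls(
            fixed=FixedEffects(
                v_pop=fx.get("v_pop", 44.61), cl_pop=fx.get("cl_pop", 5.73),
                ka_pop=fx.get("ka_pop", KA_FIXED),
                tlag_pop=fx.get("tlag_pop", 0.0),
            ),
            covariate_effects=tuple(
                CovariateEffect(**e) for e in d.get("covariate_effects", [])
            ),
            random_effects=RandomEffectsSpec(
                omega_v=re_.get("omega_v", 0.77),
                omega_cl=re_.get("omega_cl", 0.28),
            ),
            error=ErrorModelSpec(kind=em.get("kind", "constant"),
                                 a=em.get("a", 2.03), b=em.get("b", 0.0)),
            structural=st.get("model", "first_order"),
            bioavailability=st.get("bioavailability", "saturable"),
            dmax=st.get("dmax", DMAX_DEFAULT), d50=st.get("d50", D50_DEFAULT),
            n_transit=st.get("n_transit", 0), ktr=st.get("ktr"),
            fixed_parameters=tuple(st.get("fixed_parameters", ("ka", "tlag"))),
        )


def _log_typical(spec: PopulationModelSpec, parameter: str,
                 cov: CovariateRecord) -> float:
    base = {
        "v": spec.fixed.v_pop, "cl": spec.fixed.cl_pop,
        "ka": spec.fixed.ka_pop,
        "tlag": spec.fixed.tlag_pop if spec.fixed.tlag_pop > 0 else None,
    }[parameter]
    if base is None:  # tlag 0: no covariate machinery on a zero lag
        return -math.inf
    out = math.log(base)
    for eff in spec.effects_on(parameter):
        try:
            out += eff.beta * eff.design_value(cov)
        except KeyError as exc:
            raise KeyError(
                f"covariate {eff.covariate!r} required by the model is missing"
            ) from exc
    return out


def individual_parameters(
    spec: PopulationModelSpec,
    covariates: CovariateRecord,
    eta: Optional[Mapping[str, float]] = None,
) -> StructuralParams:
    """Map population spec + covariates + random effects to StructuralParams.

    ``eta`` maps parameter names ('v', 'cl') to their log-scale random
    effects; omitted parameters use eta = 0.
    """
    eta = dict(eta or {})

    def one(parameter: str) -> float:
        lt = _log_typical(spec, parameter, covariates)
        if lt == -math.inf:
            return 0.0
        return math.exp(lt + eta.get(parameter, 0.0))

    tlag = one("tlag") if spec.structural == "first_order_lag" else 0.0
    dmax, d50 = spec.dmax, spec.d50
    if spec.bioavailability == "constant":
        # dose-independent F = 1 (folded into the apparent V and Cl):
        # realised as Dmax = D50 -> infinity so F(dose) -> 1 for any dose
        dmax = d50 = 1e12
    params = StructuralParams(
        v=one("v"), cl=one("cl"), ka=one("ka"), tlag=tlag,
        dmax=dmax, d50=d50,
        n_transit=spec.n_transit if spec.structural == "transit" else 0,
        ktr=spec.ktr if spec.structural == "transit" else None,
    )
    return params


def residual_sd(prediction, error: ErrorModelSpec):
    """Residual standard deviation at a model prediction (ug/mL)."""
    f = np.asarray(prediction, dtype=float)
    if error.kind == "constant":
        out = np.full_like(f, error.a)
    elif error.kind == "proportional":
        out = error.b * np.abs(f)
    else:
        out = np.sqrt(error.a ** 2 + (error.b * f) ** 2)
    return float(out) if out.ndim == 0 else out


def observation_loglik(y, prediction, error: ErrorModelSpec):
    """Gaussian log-density of observation(s) y given prediction(s)."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(prediction, dtype=float)
    sd = np.asarray(residual_sd(f, error), dtype=float)
    if np.any(sd <= 0):
        raise ValueError("residual SD must be strictly positive")
    out = -0.5 * (_LOG_2PI + 2.0 * np.log(sd) + ((y - f) / sd) ** 2)
    return float(out) if out.ndim == 0 else out
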