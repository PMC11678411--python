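"""Model/Results interface over the SAEM engine.

``GabapentinPKModel`` binds a dataset to a population-model specification;
``fit()`` runs SAEM and returns a ``PopPKResults`` carrying the estimates,
their uncertainties (on demand), likelihood criteria, empirical Bayes
estimates, shrinkage and a text ``summary()``.  Simulation and the
diagnostic layer (residuals, VPC, bootstrap) hang off these two objects.

    >>> model = GabapentinPKModel(dataset)          # default final-model spec
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .dataset import PKDataset, read_dataset
from .population import PopulationModelSpec
from .saem import (
    FitResult, LikelihoodResult, SAEMSettings, empirical_bayes, fit_saem,
    loglik_importance_sampling, shrinkage, standard_errors,
)

__all__ = ["GabapentinPKModel", "PopPKResults"]


class GabapentinPKModel:
    """A population PK model bound to a TDM dataset.

    Parameters
    ----------
    dataset : PKDataset
    spec : PopulationModelSpec, optional
        Defaults to the final gabapentin model structure: one-compartment,
        first-order absorption (ka fixed), saturable bioavailability,
        SCr-on-Cl covariate, random effects on V and Cl, constant error.
    """

    def __init__(self, dataset: PKDataset,
                 spec: Optional[PopulationModelSpec] = None):
        from .cohort import default_truth_spec
        self.dataset = dataset
        self.spec = spec if spec is not None else default_truth_spec()

    @classmethod
    def from_csv(cls, path, spec: Optional[PopulationModelSpec] = None,
                 column_map: Optional[Dict[str, str]] = None
                 ) -> "GabapentinPKModel":
        """Build from a NONMEM-style event-record CSV/TSV."""
        return cls(read_dataset(path, column_map=column_map), spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       spec: Optional[PopulationModelSpec] = None
                       ) -> "GabapentinPKModel":
        """Build from an in-memory event-record table (same columns as the file)."""
        import io
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_dataset(buf), spec)

    def fit(self, settings: Optional[SAEMSettings] = None,
            seed: Optional[int] = None,
            compute_likelihood: bool = True,
            n_is_samples: int = 1000) -> "PopPKResults":
        """Estimate by SAEM; optionally attach the IS marginal likelihood."""
        settings = settings or SAEMSettings()
        if seed is not None:
            settings = replace(settings, seed=seed)
        fit = fit_saem(self.dataset, self.spec, settings)
        if compute_likelihood:
            fit.likelihood = loglik_importance_sampling(
                self.dataset, fit.spec, n_samples=n_is_samples,
                seed=settings.seed + 10_000,
            )
        return PopPKResults(self, fit)

    def simulate(self, spec: Optional[PopulationModelSpec] = None,
                 seed: int = 0) -> PKDataset:
        """Simulate a dataset under ``spec`` with this dataset's design."""
        from .cohort import simulate_concentrations
        ds, _ = simulate_concentrations(
            self.dataset.subjects, spec or self.spec, seed=seed,
        )
        return ds


class PopPKResults:
    """Results of a SAEM fit: estimates, uncertainty, diagnostics access."""

    def __init__(self, model: GabapentinPKModel, fit: FitResult):
        self.model = model
        self.fit = fit

    # -- estimates ----------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        """Estimated parameters (free ones only), as a named Series."""
        return pd.Series(
            {n: self.fit.estimates[n] for n in self.fit.free_parameters},
            name="estimate",
        )

    @property
    def spec(self) -> PopulationModelSpec:
        """The model spec with final estimates plugged in."""
        return self.fit.spec

    # -- uncertainty --------------------------------------------------------

    def compute_se(self, seed: int = 0, n_samples: int = 500) -> pd.Series:
        """Standard errors via the CRN finite-difference Hessian (cached)."""
        if self.fit.se is None:
            standard_errors(self.fit, self.model.dataset, seed=seed,
                            n_samples=n_samples)
        return pd.Series(self.fit.se, name="se")

    @property
    def bse(self) -> pd.Series:
        return self.compute_se()

    @property
    def rse(self) -> pd.Series:
        """Relative standard errors, percent."""
        self.compute_se()
        return pd.Series(self.fit.rse, name="rse_pct")

    # -- likelihood ---------------------------------------------------------

    @property
    def likelihood(self) -> LikelihoodResult:
        if self.fit.likelihood is None:
            self.fit.likelihood = loglik_importance_sampling(
                self.model.dataset, self.fit.spec,
                seed=self.fit.seed + 10_000,
            )
        return self.fit.likelihood

    @property
    def ofv(self) -> float:
        return self.likelihood.ofv

    @property
    def aic(self) -> float:
        return self.likelihood.aic

    @property
    def bic(self) -> float:
        return self.likelihood.bic

    # -- random effects -----------------------------------------------------

    @property
    def ebes(self) -> pd.DataFrame:
        """Empirical Bayes estimates of the random effects, per subject."""
        if self.fit.ebes is None:
            empirical_bayes(self.fit, self.model.dataset)
        return pd.DataFrame(
            self.fit.ebes,
            index=[s.id for s in self.model.dataset.subjects],
            columns=[f"eta_{p}" for p in self.fit.ebe_parameters],
        )

    @property
    def eta_shrinkage(self) -> pd.Series:
        """Eta-shrinkage (%) per random effect."""
        ebes = self.ebes  # ensures EBEs exist
        omegas = [
            self.fit.spec.random_effects.omega(p)
            for p in self.fit.ebe_parameters
        ]
        shr = shrinkage(ebes.to_numpy(), omegas)
        self.fit.shrinkage_pct = {
            p: s for p, s in zip(self.fit.ebe_parameters, shr)
        }
        return pd.Series(self.fit.shrinkage_pct, name="shrinkage_pct")

    # -- diagnostics --------------------------------------------------------

    def residuals(self, n_sim: int = 1000, seed: int = 0):
        """Population/individual weighted residual table (PWRES, IWRES)."""
        from .diagnostics import residuals
        return residuals(self.fit, self.model.dataset, n_sim=n_sim, seed=seed)

    def vpc(self, n_rep: int = 500, bins: int = 6, seed: int = 0):
        """Visual predictive check under the fitted model."""
        from .diagnostics import vpc
        return vpc(self.fit, self.model.dataset, n_rep=n_rep, bins=bins,
                   seed=seed)

    def bootstrap(self, n_rep: int = 1000, seed: int = 0,
                  settings: Optional[SAEMSettings] = None):
        """Nonparametric (subject-resampling) bootstrap of the estimates."""
        from .diagnostics import bootstrap
        return bootstrap(self.model.dataset, self.model.spec, n_rep=n_rep,
                         seed=seed, settings=settings or self.fit.settings)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Fixed-width text summary in the style of a popPK run record."""
        ds = self.model.dataset
        spec = self.fit.spec
        lines = []
        w = 64
        lines.append("=" * w)
        lines.append("Population PK fit (SAEM) - oral gabapentin".center(w))
        lines.append("=" * w)
        lines.append(f"Subjects: {ds.n_subjects:<8d} Observations: {ds.n_observations}")
        lines.append(f"Structural: {spec.structural}, bioavailability {spec.bioavailability}"
                     f" (Dmax {spec.dmax:g}, D50 {spec.d50:g})")
        lines.append(f"Error model: {spec.error.kind}")
        if self.fit.likelihood is not None:
            lk = self.fit.likelihood
            lines.append(
                f"OFV {lk.ofv:.2f}   AIC {lk.aic:.2f}   BIC {lk.bic:.2f}"
                f"   ({lk.method}, MC-SE {lk.mc_se:.2f})"
            )
        lines.append("-" * w)
        lines.append(f"{'Parameter':<18}{'Estimate':>12}{'RSE (%)':>12}")
        lines.append("-" * w)
        rse = self.fit.rse or {}
        for n in self.fit.free_parameters:
            r = rse.get(n)
            rtxt = f"{r:.1f}" if r is not None and np.isfinite(r) else "-"
            lines.append(f"{n:<18}{self.fit.estimates[n]:>12.4g}{rtxt:>12}")
        fixed = []
        if "ka" in spec.fixed_parameters:
            fixed.append(f"ka = {spec.fixed.ka_pop:g} 1/h")
        if spec.structural == "first_order_lag":
            fixed.append(f"Tlag = {spec.fixed.tlag_pop:g} h")
        if fixed:
            lines.append("-" * w)
            lines.append("Fixed: " + ", ".join(fixed))
        if self.fit.shrinkage_pct:
            shr = ", ".join(
                f"eta_{p}: {v:.1f}%" for p, v in self.fit.shrinkage_pct.items()
                if v is not None
            )
            lines.append("Shrinkage: " + shr)
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:
        est = ", ".join(f"{n}={self.fit.estimates[n]:.3g}"
                        for n in self.fit.free_parameters)
        return f"<PopPKResults: {est}>"
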