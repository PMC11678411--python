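"""Goodness-of-fit residuals, visual predictive check and bootstrap.

The validation layer of the popPK analysis:

* IWRES: individual weighted residuals, (y - f(psi_i)) / sd(f(psi_i)),
  with psi_i at the empirical Bayes estimates.
* PWRES: population weighted residuals, (y - E[y]) / SD[y], with the
  population moments obtained by Monte-Carlo simulation under the fitted
  model (correct under the nonlinear bioavailability, where a
  linearisation would not be).
* VPC: percentile bands of datasets simulated with the original design,
  with confidence intervals across replicates, against the observed
  percentiles in time bins.
* Bootstrap: subjects resampled with replacement to the original cohort
  size; each replicate refitted from the original initial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .population import PopulationModelSpec
from .saem import FitResult, SAEMSettings, empirical_bayes, fit_saem, _Problem

__all__ = [
    "ResidualTable",
    "VPCResult",
    "BootstrapResult",
    "residuals",
    "vpc",
    "bootstrap",
    "plot_gof",
    "plot_vpc",
]


@dataclass
class ResidualTable:
    """Per-observation residual diagnostics."""

    table: pd.DataFrame  # columns: subject, time, dv, pred_pop, pred_ind, pwres, iwres

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VPCResult:
    """Binned observed percentiles and simulated prediction bands."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame  # columns p5, p50, p95 per bin
    simulated: pd.DataFrame  # columns p5, p50, p95 (medians across reps)
    ci_low: pd.DataFrame  # 2.5% CI bound of each simulated percentile
    ci_high: pd.DataFrame  # 97.5% CI bound
    n_replicates: int
    merged_bins: List[str] = field(default_factory=list)


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap medians and percentile intervals."""

    summary: pd.DataFrame  # index parameter; columns median, ci_low, ci_high
    n_attempted: int
    n_converged: int
    replicates: pd.DataFrame = None  # one row per converged replicate
    unstable: bool = False


def _individual_predictions(fit: FitResult, dataset: PKDataset) -> np.ndarray:
    """Predictions at the EBEs, one value per observation."""
    if fit.ebes is None:
        empirical_bayes(fit, dataset)
    prob = _Problem(dataset, fit.spec)
    phi = prob.prior_mean() + fit.ebes
    return prob.predict(phi)


def residuals(fit: FitResult, dataset: PKDataset, n_sim: int = 1000,
              seed: int = 0) -> ResidualTable:
    """PWRES/IWRES table; one row per observation, in dataset order."""
    prob = _Problem(dataset, fit.spec)
    rng = np.random.default_rng(seed)
    # individual predictions and IWRES
    f_ind = _individual_predictions(fit, dataset)
    sd_ind = np.sqrt(prob.residual_var(f_ind))
    iwres = (prob.y - f_ind) / sd_ind
    # population moments by simulation
    om = prob.omega
    mean = prob.prior_mean()
    sims = np.empty((n_sim, prob.n_obs))
    for r in range(n_sim):
        phi = mean + rng.standard_normal(mean.shape) * om
        f = prob.predict(phi)
        sims[r] = f + np.sqrt(prob.residual_var(f)) * rng.standard_normal(prob.n_obs)
    e_pop = sims.mean(axis=0)
    sd_pop = sims.std(axis=0, ddof=1)
    pwres = (prob.y - e_pop) / sd_pop
    f_pop = prob.predict(mean)  # typical predictions (eta = 0)
    table = pd.DataFrame({
        "subject": [prob.subject_ids[i] for i in prob.obs_subj],
        "time": prob.t_obs,
        "dv": prob.y,
        "pred_pop": f_pop,
        "pred_ind": f_ind,
        "pwres": pwres,
        "iwres": iwres,
    })
    return ResidualTable(table=table)


def _percentiles(values: np.ndarray, qs=(5, 50, 95)) -> np.ndarray:
    return np.percentile(values, qs)


def vpc(fit: FitResult, dataset: PKDataset, n_rep: int = 500, bins: int = 6,
        seed: int = 0, quantiles=(5, 50, 95)) -> VPCResult:
    """Visual predictive check with equal-count time bins.

    Simulates ``n_rep`` datasets under the fitted model with the original
    design (doses, sample times, covariates), computes the 5/50/95th
    percentiles per time bin in each replicate, and summarises each
    percentile by its median and 95% confidence band across replicates.
    Bins with fewer than 5 observations are merged with their neighbour.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100 for stable percentile bands")
    prob = _Problem(dataset, fit.spec)
    rng = np.random.default_rng(seed)
    t = prob.t_obs
    # equal-count bin edges on time since first dose
    edges = np.unique(np.percentile(t, np.linspace(0, 100, bins + 1)))
    if len(edges) < 2:  # all observation times identical: one bin
        edges = np.array([t.min() - 1e-9, t.max() + 1e-9])
    merged: List[str] = []
    while True:
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1,
                      0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.where(counts < 5)[0]
        if small.size == 0 or len(edges) <= 2:
            break
        j = small[0]
        drop = j + 1 if j + 1 < len(edges) - 1 else j
        merged.append(f"bin {j} merged (only {counts[j]} observations)")
        edges = np.delete(edges, drop)
    n_bins = len(edges) - 1
    mids = 0.5 * (edges[:-1] + edges[1:])

    obs_pct = np.array([
        _percentiles(prob.y[idx == b], quantiles) for b in range(n_bins)
    ])
    sim_pct = np.empty((n_rep, n_bins, len(quantiles)))
    mean = prob.prior_mean()
    om = prob.omega
    for r in range(n_rep):
        phi = mean + rng.standard_normal(mean.shape) * om
        f = prob.predict(phi)
        y = f + np.sqrt(prob.residual_var(f)) * rng.standard_normal(prob.n_obs)
        for b in range(n_bins):
            sim_pct[r, b] = _percentiles(y[idx == b], quantiles)
    cols = [f"p{q}" for q in quantiles]
    return VPCResult(
        bin_edges=edges,
        bin_mid=mids,
        observed=pd.DataFrame(obs_pct, columns=cols),
        simulated=pd.DataFrame(np.median(sim_pct, axis=0), columns=cols),
        ci_low=pd.DataFrame(np.percentile(sim_pct, 2.5, axis=0), columns=cols),
        ci_high=pd.DataFrame(np.percentile(sim_pct, 97.5, axis=0), columns=cols),
        n_replicates=n_rep,
        merged_bins=merged,
    )


def bootstrap(dataset: PKDataset, spec: PopulationModelSpec, n_rep: int = 1000,
              seed: int = 0, settings: Optional[SAEMSettings] = None
              ) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, summarise.

    Each replicate draws ``n_subjects`` subjects with replacement
    (unstratified) and refits from the original initial values in
    ``spec``.  Replicates whose fit raises are counted as failures and
    excluded; the result is flagged unstable when more than 20% fail.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    settings = settings or SAEMSettings()
    rng = np.random.default_rng(seed)
    n = dataset.n_subjects
    rows = []
    failures = 0
    for r in range(n_rep):
        pick = rng.integers(0, n, size=n)
        subjects = [
            replace(dataset.subjects[j], id=f"B{r}_{k}")
            for k, j in enumerate(pick)
        ]
        bs = PKDataset(subjects=subjects, provenance=f"bootstrap rep {r}")
        try:
            fit = fit_saem(bs, spec, replace(settings, seed=seed + 100_003 * (r + 1)))
            rows.append({n2: fit.estimates[n2] for n2 in fit.free_parameters})
        except Exception:
            failures += 1
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("every bootstrap replicate failed to fit")
    summary = pd.DataFrame({
        "median": reps.median(),
        "ci_low": reps.quantile(0.025),
        "ci_high": reps.quantile(0.975),
    })
    return BootstrapResult(
        summary=summary,
        n_attempted=n_rep,
        n_converged=len(reps),
        replicates=reps,
        unstable=failures > 0.2 * n_rep,
    )


# ---------------------------------------------------------------------------
# plotting (matplotlib, static exports)
# ---------------------------------------------------------------------------

def plot_gof(res: ResidualTable, path=None):
    """Observation-vs-prediction and weighted-residual panels."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = res.table
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, pred, label in zip(axes[0], ("pred_pop", "pred_ind"),
                               ("Population prediction", "Individual prediction")):
        ax.plot(t[pred], t["dv"], "o", ms=3, alpha=0.6)
        lim = [0, max(t["dv"].max(), t[pred].max()) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(label + " (ug/mL)")
        ax.set_ylabel("Observed (ug/mL)")
    for ax, resid, label in zip(axes[1], ("pwres", "iwres"),
                                ("PWRES", "IWRES")):
        ax.plot(t["time"], t[resid], "o", ms=3, alpha=0.6)
        ax.axhline(0, color="k", lw=1)
        ax.set_xlabel("Time since first dose (h)")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_vpc(v: VPCResult, dataset: Optional[PKDataset] = None, path=None):
    """VPC plot: simulated bands, observed percentiles, optional raw data."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for col in v.simulated.columns:
        ax.fill_between(v.bin_mid, v.ci_low[col], v.ci_high[col],
                        alpha=0.25, color="tab:blue")
        ax.plot(v.bin_mid, v.simulated[col], "-", color="tab:blue", lw=1)
        ax.plot(v.bin_mid, v.observed[col], "k-", lw=1.5)
    if dataset is not None:
        ts, ys = [], []
        for s in dataset.subjects:
            for o in s.observations:
                ts.append(o.time)
                ys.append(o.concentration)
        ax.plot(ts, ys, "o", ms=3, color="tab:blue", alpha=0.5)
    ax.set_xlabel("Time since first dose (h)")
    ax.set_ylabel("Concentration (ug/mL)")
    ax.set_title(f"Visual predictive check ({v.n_replicates} replicates)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
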