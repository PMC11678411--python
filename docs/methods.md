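# Methods

## The model

`gabapk` implements a population pharmacokinetic model for oral
gabapentin estimated from sparse therapeutic-drug-monitoring (TDM)
concentrations. The structural model is one-compartment with first-order
elimination and first-order oral absorption, with a saturable,
dose-dependent bioavailability

F(Dose) = Dmax / (D50 + Dose),  Dmax = 823, D50 = 1120,

both fixed to literature values. The concentration after a dose history
{(t_d, D_d)} is the superposition

C(t) = Σ_d F(D_d) · D_d · ka / (V (ka − ke)) · (e^{−ke τ_d} − e^{−ka τ_d}),
τ_d = t − t_d − Tlag,

with ke = Cl/V; the analytic limit F·D·ka·τ·e^{−ka τ}/V replaces the
general form when |ka − ke|/ka < 1e−8 (catastrophic cancellation
otherwise). Doses in mg and volumes in L give mg/L, numerically equal to
µg/mL. Candidate alternatives kept for model comparison: a lagged
first-order model (Tlag fixed at 0.31 h), a transit-compartment chain
(n serial compartments at rate ktr feeding an absorption compartment that
empties at ka), and a dose-independent F.

The transit chain is evaluated by its exact inverse Laplace transform:
the repeated transit pole of order n is expanded analytically and the
simple poles at ka and ke are nudged apart by 1e−7 relative when they
collide with ktr or each other. This keeps the evaluation exact to ~1e−8
(verified against `solve_ivp` in the tests) while remaining a pure
vectorised array expression, which SAEM needs.

### Statistical layer

Individual parameters are log-normal with power-law covariate effects:

log ψ_i = log ψ_pop + Σ_c β_c x_ci + η_i,  η_i ~ N(0, ω²)

where x_ci = log(cov_i / ref) for continuous covariates (ref defaults to
the cohort arithmetic mean; the final gabapentin model centres serum
creatinine at 1.3 mg/dL) and a 0/1 indicator for categorical covariates
(reference = largest class; the 4-level obesity/diabetes category expands
into three indicators). Random effects exist on V and Cl only; ka and
Tlag are fixed. The residual model is Gaussian with SD `a` (constant),
`b·f` (proportional) or sqrt(a² + (b f)²) (combined); the final model is
constant with a = 2.03 µg/mL. A constant error model admits negative
simulated concentrations; the simulator keeps them by default for
statistical fidelity (an optional clip at 0 exists for cosmetic output).

Final published estimates, used both as defaults and as the synthetic
generating truth: V 44.61 L, Cl 5.73 L/h, ka 0.778 h⁻¹ (fixed),
β_Cl,SCr −0.89, ω_V 0.77, ω_Cl 0.28, a 2.03 µg/mL.

## SAEM estimation

`fit_saem` is a stochastic approximation EM:

* **E-step** — Metropolis–Hastings on each subject's log-parameters
  φ_i, three kernels per sweep: an independent draw from the conditional
  prior N(Xθ, Ω), a component-wise random walk, and a joint random walk.
  Random-walk scales adapt every 20 burn-in iterations toward a 0.3
  acceptance rate. All subjects update vectorised in one array pass.
* **SA-step** — Robbins–Monro averaging of the sufficient statistics of
  the log-linear model (X'φ, φ'φ, per-observation squared residuals)
  with step 1 during burn-in and 1/(k − n_burnin) during smoothing.
* **M-step** — per-parameter weighted least squares gives log ψ_pop and
  the β's in closed form; ω² is the residual mean square; the constant
  (or proportional) error parameter has a closed-form update, the
  combined model a 2-d Nelder–Mead on the averaged statistics. During
  burn-in a simulated-annealing floor (ω²_k ≥ 0.95 ω²_{k−1}, same for
  a²) prevents premature variance collapse. Coefficients on parameters
  without random effects (e.g. a covariate tested on the fixed ka) are
  updated by a damped numeric minimisation of the weighted residual sum
  of squares — a SAEM variant with a numerical M-step for that block.

Defaults: 300 burn-in + 200 smoothing iterations, 1 chain. The
replicated recovery experiments use 600 + 400 because V is the
slowest-mixing direction on the sparse steady-state design (large ω_V
combined with a small peak–trough contrast); at 300 + 200 the V-side
estimates are visibly under-converged there. Identical seed, settings
and data give bit-identical trajectories.

Initial values are the previously reported literature estimates
(V 45.4 L, Cl 6.31 L/h scale; the package defaults carry the final
estimates and any spec can override them).

### Likelihood, SEs, EBEs

* **OFV** (−2 log L) by per-subject importance sampling: a multivariate
  t (df 5) proposal centred on the conditional mode with
  Laplace-approximation scale, 1000 samples/subject by default; the
  Monte-Carlo SE is reported and subjects with effective sample size
  below 5% are flagged. AIC = OFV + 2P; BIC = OFV + P log(N_obs) with
  N_obs the total observation count (the mixed-effects BIC variant used
  by some tools differs and is deliberately not replicated).
* **Oracle** — adaptive tensor-product Gauss–Hermite quadrature (≤2
  random effects) provides a deterministic cross-check; the test suite
  requires agreement within 0.5 OFV units.
* **Standard errors** — finite-difference Hessian of the
  importance-sampled log-likelihood with common random numbers (the
  proposal modes, scales and draws are frozen at the fitted model, and
  the frozen draws are re-expressed relative to each perturbed prior
  mean so the integrand stays smooth in the parameters). Non-positive
  curvature is flagged per parameter, never papered over.
  RSE% = 100·SE/|estimate|.
* **EBEs** — per-subject MAP of η by Nelder–Mead;
  η-shrinkage = 100·(1 − SD(EBE)/ω), with SD using ddof = 1.

## Covariate selection

Covariates are tested in the clinical-question order: renal indices
(CrCl, SCr, eGFR, AKI) on Cl; body-size metrics (WT, IBW, ABW, LBW, BMI,
obesity) on V; diabetes-related covariates (diabetes, FPG, combined
metabolic category) on ka and V; then a correlation screen of remaining
covariates against the random effects (Pearson on the log scale for
continuous, one-way ANOVA for categorical, p ≤ 0.01). A covariate enters
only when three gates pass jointly: ΔOFV ≥ 3.84, Wald p ≤ 0.01 and the
EBE-correlation p ≤ 0.01. The Wald statistic is skipped (recorded as
"not evaluated") when the ΔOFV gate has already failed — the conjunction
cannot accept regardless. For a parameter without a random effect the
EBE-correlation gate is undefined and passes through with a note. Within
a stage the accepted covariate with the largest ΔOFV wins; ties break
toward the covariate with the fewest derived inputs (SCr before CrCl
before eGFR), and only one member of a collinear family may enter a
parameter. Backward deletion removes any covariate whose deletion raises
the OFV by less than 6.63. Base and augmented OFVs use importance
sampling with a common seed, keeping Monte-Carlo noise (SE ≈ 0.3–0.5)
well below the 3.84 gate. Within a stage, candidates whose ΔOFV lies
within 2 units of the best (the scale of the residual evaluation noise)
count as tied, so that the tie-break — not Monte-Carlo wobble — decides
between near-collinear covariates such as the renal indices.

Multi-level categories use a joint Wald chi-square over the indicator
block with a diagonal-covariance approximation (noted in the result);
the ΔOFV gate remains 3.84 for comparability with the single-covariate
gates.

## Diagnostics

* **IWRES** = (y − f(ψ_EBE))/sd(f); **PWRES** = (y − E[y])/SD[y] with
  population moments by Monte-Carlo simulation (1000 draws by default) —
  a linearisation would be wrong under the nonlinear F.
* **VPC** — equal-count time bins (default 6, counted on time since
  first dose; bins under 5 observations merge with a neighbour);
  simulated 5/50/95th percentile bands with 95% confidence intervals
  across replicates (default 500), observed percentiles overlaid.
* **Bootstrap** — subjects resampled with replacement to the original
  cohort size, unstratified; each replicate refits from the original
  initial values; medians and 2.5–97.5 percentiles over converged
  replicates; >20% failures flags the result unstable. Default 1000
  replicates (desk-scale runs reduce this).

## Synthetic cohort generator

The generator emulates the study cohort the model was built on: 82
subjects; age ~ truncated-normal(65.7, 16.4) on [22, 93] years; weight
(84.3, 25.9) on [44.2, 195] kg; height (167.1, 9.8) on [149.9, 187.9]
cm; 62.2% female; 7.3% black, 1.2% asian, 2.4% other; SCr log-normal
moment-matched to mean 1.3, SD 1.0, truncated to [0.4, 3.8] mg/dL
(log-normal because SCr is positive and right-skewed; only mean ± SD and
range are known); FPG (127.6, 78.2) on [76, 251] mg/dL; 31.7% diabetic;
21.9% AKI. Truncated draws use inverse-CDF sampling, so bounds hold
exactly. Diabetic subjects get multiplicative shifts (+10% weight, +35%
FPG, +15% SCr, clipped back into the truncation bounds) reflecting the
reported heavier, more hyperglycaemic, renally worse diabetic stratum;
all other covariates are independent because no correlation structure is
reported. The dose menu {100:.05, 200:.15, 300:.45, 400:.15, 600:.10,
800:.05, 900:.03, 1200:.02} reproduces the printed median (300 mg) and
range (100–1200 mg); regimens are q8/q12/q24 h (weights .5/.3/.2), 1–5
days of history, and 1–2 samples per subject (0.85/0.15) drawn uniformly
within a dosing interval after ≥24 h of dosing — matching the reported
~1.15 concentrations per patient.

What the generator does **not** emulate: longitudinal SCr trajectories
(AKI is a flag, not a mechanism), adherence/dosing irregularities,
within-subject occasion effects, assay censoring at the quantitation
limit, and any covariate correlation beyond the diabetes shifts. Passing
recovery tests therefore demonstrate estimator correctness under the
stated statistical model, not robustness to real-data artefacts.

## Validation experiments and problem sizes

* **Parameter recovery** — 10 replicate cohorts of 100 subjects on a
  rich steady-state design (300 mg q8h for 48 h, samples 1/3/6/8 h after
  the last dose), generated from the final published model and refitted;
  the median of each parameter across replicates is compared with the
  generating value. These sizes give the median ≈2–5% Monte-Carlo spread
  while keeping the whole experiment under a minute.
* **Oracle equivalence** — importance sampling vs Gauss–Hermite on
  8–20-subject problems across four model variants; closed form vs ODE
  integration on 100 random parameter/dosing draws at 1e−8 relative.
* **Selection calibration** — the acceptance conjunction applied to a
  pure-noise covariate (age) on 100 simulated 82-subject cohorts
  (expected acceptance ≤5%) and to the true SCr effect on 25 cohorts at
  the same design scale (expected ≥80%).
* **End-to-end** — the full pipeline (structural comparison, error-model
  comparison by BIC, staged covariate search, backward deletion) on five
  seeds; the published model (first-order absorption, saturable F,
  constant error, SCr on Cl as sole covariate) should win in the
  majority.

In the workflow's structural and error-model screens, the first
candidate (the literature-informed base: first-order absorption, no
lag, saturable F; constant error) acts as the reference, and a
challenger displaces it only when its BIC is better by more than 3.84 —
the same strength of evidence the covariate gates demand. Between
near-equivalent candidates (lag vs no lag differ only through a fixed
0.31 h shift; the two F models are barely distinguishable when most
subjects receive 300 mg) a plain argmax over BIC would be decided by
Monte-Carlo noise rather than by the data.

Screening fits inside the workflow use reduced SAEM settings
(150 + 100 by default) — model ranking is insensitive to the residual
Monte-Carlo wobble at these sizes, and it keeps a full workflow run in
the minutes range on one core.

## Numerical choices and edge cases

* ω is floored at 1e−4 (a degenerate random effect stays numerically
  proper); the proportional error SD uses max(|f|, 0.05) µg/mL to stay
  defined near zero predictions, where a proportional model is ill-posed
  anyway.
* Event times are re-anchored at read time so 0 h is each subject's
  first recorded dose; dose rows must be time-sorted.
* Devine IBW clamps the height term at 60 inches (with a warning); the
  Cockcroft–Gault weight switches to IBW at WT ≥ 1.3·IBW. The MDRD
  coefficient is the IDMS-traceable 175.
* AKI from an SCr series is a >0.3 mg/dL rise over the minimum of the
  preceding 48 h; with no prior value in the window the flag is False
  (the change cannot be demonstrated).
* Files are written at 17 significant digits and parsed with the
  round-trip float option, so write→read is bit-identical.

## Known limitations

* No inter-occasion variability, no correlated random effects
  (off-diagonal Ω), no two-compartment disposition, no censoring (BLQ)
  likelihood.
* The Wald covariance for multi-level categorical blocks ignores
  off-diagonal terms.
* Real-data objective-function values cannot be reproduced: the hospital
  TDM dataset is not public, and all quantitative claims here are about
  synthetic-data recovery.
* The quadrature oracle supports at most two random effects — exactly
  the final model's structure; it is a test oracle, not a production
  estimator.
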