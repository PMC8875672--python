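# Methods

## Structural models and priors

Four drugs are supported, each with the population model of the classic
hospital TDM setting. All internal computation uses L, h, mg, mg/L.

| drug | model | estimated parameters | fixed constants |
|---|---|---|---|
| amikacin | 1-cmt IV infusion | CLslope, CLnr (mL/min/kg), Vnr (L/kg) | — |
| vancomycin | 2-cmt IV infusion | CLslope, CLnr (mL/min/kg), Vnr (L/kg), k12, k21 (1/h) | — |
| theophylline | 1-cmt first-order oral | CLnr (mL/h/kg), Vnr (L/kg) | ka 0.27/h, F 1 |
| phenytoin | Michaelis–Menten, zero-order input | Vmax (mg/d), km (mg/L), Vnr (L/kg) | CLslope 0.01, F 0.92 |

Covariate equations: `CL = CLslope·CrCl(L/h) + CLnr·LBW·u` with `u`
converting CLnr's registry unit to L/h/kg (0.06 for mL/min/kg, 0.001 for
mL/h/kg); `V = Vnr·LBW`. Lean body weight uses the sex-specific equations
`1.10·W − 128·(W/H)²` (male) and `1.07·W − 148·(W/H)²` (female) — the
standard LBW form of the era this prior set comes from; the function is a
single swappable unit. Creatinine clearance is Cockcroft–Gault on LBW with
the 0.85 female factor.

Two registry entries needed interpretation. Phenytoin's Vmax is treated as
a **total** maximum elimination rate in mg/day (a 500 mg/kg/day rate would
be physiologically impossible; 500 mg/day is the textbook adult value) and
is converted to mg/h at the model boundary. Phenytoin's volume is
allometric, `V = Vnr·70·(TBW/70)^0.6`, equal to `Vnr·TBW` at 70 kg.

Between-subject variability is lognormal, `P = mean·e^η`, `ω² = ln(CV²+1)`,
so the registry "mean" is the natural-scale median; the arithmetic mean
`mean·e^{ω²/2}` is never used. The registry Lower/Upper bounds truncate
**virtual-patient sampling** (rejection sampling); the estimation prior is
the untruncated lognormal — bounding the estimation was tested and has no
measurable effect, because posteriors almost never reach the bounds.

## Forward kernels

The three linear models are evaluated in closed form as sums of
exponential modes superposed over the dose schedule (infusions handled
exactly during and after the input window). Steady state multiplies each
mode's completed-dose tail by the accumulation factor `1/(1 − e^{−λτ})`;
the profile is periodic, and times beyond one interval are reduced modulo
τ. The Bateman kernel switches to the `ka → ke` limiting form
`F·D·ka·t·e^{−ka t}/V` when `|ka − ke| < 1e-8·ke`.

Phenytoin integrates `dA/dt = input·F − [Vmax·C/(km+C) + CL_lin·C]`,
`C = A/V`. Two integration routes exist: an adaptive solver
(`scipy.solve_ivp`, segment-by-segment between input discontinuities;
rtol 1e-8/atol 1e-10 for truth generation) and a fixed-step RK4 vectorized
over patients (step 0.1 h inside the samplers — the elimination time scale
is ~10 h, so the local error is far below assay noise; step 0.05 h or the
adaptive route for final predictions). The two agree to ~1e-8 relative on
the label regimen.

All kernels broadcast over leading parameter axes and are holomorphic in
the parameters, so **complex-step differentiation** (step 1e-150) gives
machine-precision gradients of the log posterior, including the
contribution of the prediction-dependent residual SD. The phenytoin
gradient is complex-step through the RK4 recursion (pure arithmetic, hence
complex-safe).

## Posterior and samplers

With observations `y_i` and estimated deviations η:

    log p(η|y) = Σ_k N(η_k; 0, ω_k²) + Σ_i N(y_i; C_i(η), σ_i²),
    σ_i = CVassay·C_i(η) + Sassay.

Two HMC flavors (both leapfrog + dual-averaging step size, target accept
0.8, diagonal mass adaptation initialized at the prior variances with one
mid-warmup re-estimation, chains started at η ~ N(0, 0.1²)):

- **Dynamic NUTS** (slice variant, max tree depth 10) for single-patient
  fits — the default `HMCEstimator` path.
- **Jittered fixed-length HMC** batched over patients×chains for the
  validation harness, where hundreds of independent 2–5-dimensional
  posteriors are sampled simultaneously; the leapfrog count is drawn
  uniformly from 1..16 each iteration. Prior-scale preconditioning makes
  these posteriors near-unit-scale, and the flavor is recorded in the
  result metadata. Divergences (|ΔH| > 1000 or non-finite) are rejected
  and counted.

Defaults are 4 chains × (2500 warmup + 2500 samples); the named `reduced`
preset (500 + 500) is used for the scaled-down study. Point estimates are
posterior medians of the pooled draws (means and 90% central intervals are
also reported but not used downstream). Convergence is flagged with
rank-normalized split R-hat (< 1.1) and bulk ESS, computed by a vectorized
implementation cross-checked against arviz in the tests; non-converged
fits are excluded from validation metrics and counted.

**MAP.** The default objective is the full negative log posterior — the
posterior mode proper, including the `log σ(C_pred)` normalization of the
heteroscedastic error model. The classical penalized least-squares
objective `Φ = Σ (y−C)²/σ̂² + Σ η²/ω²` (which omits that term) is available
via `objective="phi"` and is always reported as `phi_`. The distinction
matters: with prediction-dependent σ the normalization term rewards
smaller predicted concentrations and shifts the mode a few percent low —
which is exactly the behavior of full-likelihood MAP engines, and what the
MAP branch of the validation study reflects. σ̂ is recomputed from the
current prediction at every objective evaluation. Optimization is
multi-start L-BFGS-B (prior mean + 2 jittered starts, jitter 0.5·ω); the
per-patient problems are independent and optimized jointly as one
block-diagonal objective.

## Virtual cohorts and the validation study

Demographics emulate an adult hospital population: height ~ N(165.1, 8.7²)
cm, weight ~ N(65.1, 10.2²) kg, age ~ N(50.2, 17.1²) y, truncated by
resampling to [140, 200], [35, 120], [18, 90]; sex Bernoulli(0.5); serum
creatinine lognormal with median 1.1 mg/dL and log-SD 0.2, truncated to
[0.4, 3.0]. The sex ratio and creatinine distribution are the package's
own choices (the cohort definition gives only height/weight/age); the
creatinine scale was set so the cohort-mean CrCl ≈ 52 mL/min, consistent
with the reported cohort-mean clearance products (CLnr·LBW ≈ 2.5,
CLslope·CrCl ≈ 45.3 mL/min — checked in the tests at 25%).

Scenarios: 4 drugs × {single dose, steady state} × {peak, trough,
peak+trough, hourly} = 32 cells, with label regimens amikacin 500 mg at
1000 mg/h q8h, vancomycin 1000 mg at 500 mg/h q12h, theophylline 200 mg
oral q12h, phenytoin 100 mg at 50 mg/h q8h, and the usual TDM sampling
times (peaks at 1/2/4/2 h).

Observations add the assay error model to the noise-free truth **without
truncation** — exactly the printed error model. A non-positive observed
value is possible where σ is large relative to the concentration
(phenytoin troughs: σ ≈ 1.2 mg/L at C ≈ 1.9) and is retained; the Gaussian
likelihood handles it. Truncating instead (redrawing until positive) was
found to bias the phenytoin single-dose cells upward by ~4–5 percentage
points.

External validation draws the truth from independently published
population models (different structures and parameterizations, proportional
or exponential residual error) and still estimates with the internal
priors — the mismatch is the point. Parameter scoring then compares
recalculated shared quantities (CL and V; Vmax/km/V for phenytoin);
vancomycin's peripheral parameters have no faithful mapping and are
excluded.

Scoring follows the one-interval-forward convention: concentrations are
predicted at the sampling times shifted by one dosing interval, with the
regimen continuing (a second dose in the single-dose case); truth is
noise-free. Steady state uses the analytic profile for linear drugs;
phenytoin's "steady state" is the 20th dose (observation) and 21st dose
(scoring), since true steady state is often not reached. MPE (%) measures
bias, RMSE (mg/L) precision, pooled over patients × evaluation times.

### Problem sizes and what the study shows

The desk-scale study uses 200 internal / 100 external patients per
scenario (300 for the phenytoin single-dose trough cell, whose per-patient
error ratios are heavy-tailed — true troughs reach ~0.2 mg/L — making its
MPE noisy at smaller n) with the reduced sampler preset. The full
1000/300-patient grid is supported through the same API.

The study validates the estimation machinery under its own generating
assumptions: the fits are Bayes-calibrated (realized parameter-error SD
equals the mean posterior SD), bias is near zero wherever sampling is
informative, precision improves with sampling density, external models
degrade performance, and MAP tracks HMC. It does **not** show performance
on real patients: real cohorts have correlated demographics, model
misspecification beyond the external-model proxy, and assay errors that
need not follow the assumed σ(C) line. Reported RMSE equals the Bayesian
error floor implied by the stated priors and assay constants; generating
conditions with less effective noise would produce proportionally smaller
RMSE at identical bias.

## Numerical choices

- ODE tolerances: rtol 1e-8/atol 1e-10 (truth, oracles), RK4 step 0.1 h
  inside samplers; both configurable.
- AUC targets: trapezoid on a 0.05 h grid over one steady-state interval
  (one code path for linear and nonlinear models; linear-model AUC error
  < 0.1%).
- Dose recommendation is proportional scaling for all drugs and target
  modes; for phenytoin it carries an explicit nonlinearity warning, and
  the recommended dose is assumed delivered with the dose-proportional
  input rate (fixed infusion duration), which closes the loop exactly for
  linear kinetics.
- Degenerate inputs: `ka = ke` switches to the limiting Bateman form;
  two-compartment discriminants are non-negative for positive
  micro-constants and guarded; negative ODE states are clipped at zero.
- Reproducibility: every stochastic entry point takes a seed;
  scenario grids spawn independent child streams per cell, so results are
  independent of execution order.

## Known limitations

- No lag times, transit absorption, protein-binding correction, or drugs
  beyond the four; no population-model fitting (individual estimation
  only).
- The linear-steady-state dataset convention stores within-interval
  observation times plus the regimen; fitting such a file outside the
  harness requires the steady-state flag (`addl` carries the history for
  phenytoin, where it matters).
- MPE on concentration ratios is heavy-tailed when true troughs approach
  zero; cell-level MPE for such cells should be read with its Monte-Carlo
  error in mind.
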