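# Methods

## The model

Total serum bilirubin (TSB) `B(t)` in a neonate, with `t` the postnatal age
(PNA) in hours and concentrations in µmol/l, follows a turnover equation

```
dB/dt = kprod(t) − kelim(t)·B(t),   B(0) = B0,
```

a zero-order production term and a first-order elimination term.  In the
first days of life both processes are still maturing: fetal red-cell turnover
elevates production, and hepatic conjugation/excretion capacity is immature.
We represent each maturation with a single exponential:

```
kprod(t) = P_ss · (1 + A_p · 2^(−t/T_p))
kelim(t) = K_ss · (1 − M_e · 2^(−t/T_e))
```

* `B0` (µmol/l) — bilirubin at birth.
* `P_ss` (µmol/l/h) — mature production rate; `A_p` (–) the fractional
  elevation at birth; `T_p` (h) the half-life of its decay.
* `K_ss` (1/h) — mature elimination rate constant; `M_e` ∈ [0,1) the
  fractional deficit at birth; `T_e` (h) the maturation half-life.

This is the minimal parameterization consistent with the physiology
(production elevated and elimination reduced at birth, both approaching
mature asymptotes).  With `A_p = M_e = 0` the model reduces to constant-rate
turnover with the closed form
`B(t) = P_ss/K_ss + (B0 − P_ss/K_ss)·e^(−K_ss t)`, used as a test oracle.

### Solving the ODE

The cumulative elimination exposure `E(t) = ∫₀ᵗ kelim` is available in closed
form, so the initial value problem has the exact integrating-factor
representation `B(t) = e^(−E(t)) (B0 + ∫₀ᵗ kprod(s) e^(E(s)) ds)`.  The
default solver evaluates the remaining (smooth, entire) production integral
with panel-wise 20-point Gauss–Legendre quadrature, panels capped at 24 h,
propagated incrementally between requested times so every exponent is
non-positive (overflow-safe).  This is effectively exact (cross-checked to
below 1e-8 relative against adaptive `scipy.integrate.quad` and against an
adaptive LSODA integration at rtol 1e-8 / atol 1e-10, which remains available
via `solve_trajectory(..., method="ivp")`) and is orders of magnitude faster,
which matters because population fitting evaluates trajectories millions of
times.  The same evaluation is compiled with numba inside the estimation hot
loop; the pure-numpy implementation is kept as the reference and the two are
asserted equal in tests.

### Covariate model

Typical values are scaled by patient covariates with standard power/
exponential forms, referenced to the development-cohort medians (2,500 g,
265 d):

```
P_ss,i = P_ss · (BW_i / 2500)^β_bw
K_ss,i = K_ss · (GA_i / 265)^β_ga · exp(β_cs · 1{cesarean})
```

Orientation chosen on physiological grounds: bilirubin production per plasma
volume *rises* as birth weight falls (shorter red-cell lifespan, higher
turnover in preterm infants), so β_bw < 0 in the default synthetic truth
(−0.4); elimination capacity matures steeply with gestational age (β_ga = 3),
and cesarean delivery slightly reduces elimination (β_cs = −0.1).  Under
these defaults a 28-week infant peaks near 290 µmol/l and a 42-week infant
near 115 µmol/l, bracketing the 250 µmol/l phototherapy threshold the way a
real perinatal cohort does.

### Random effects and residual error

Selected parameters carry log-normal between-subject variability:
`θ_i = θ_typical · e^(η_i)`, `η_i ~ N(0, Ω)`.  By default only `B0`, `P_ss`
and `K_ss` carry random effects; the maturation shape parameters
(`A_p, T_p, M_e, T_e`) are population-level.  With 2–4 measurements per
neonate a richer random-effects structure is not identifiable at the
individual level; the subset is configurable.

Residual error is proportional: `w_ij = f_ij (1 + σ ε_ij)`, `ε ~ N(0,1)`,
i.e. SD `σ·f`.  Clinical TSB variability (biological plus laboratory) is of
the order 5–15% CV, hence the default initial `σ = 0.10`.  One consequence
worth knowing: because the −2 log-likelihood contains `log(σ f)²`, a MAP fit
that can interpolate its data sits slightly *below* the observations — the
bias is O(σ²) (≈1% at σ = 0.10).  This is a property of full maximum
likelihood with proportional error, not an implementation artifact, and is
visible in the noise-free self-consistency tests.

## Population estimation (Laplace)

The marginal likelihood integrates the random effects out.  We use the
Laplace approximation: for each subject the −2 log joint

```
L_i(η) = Σ_j [ (w_ij − f_ij)²/(σ f_ij)² + log 2π(σ f_ij)² ]
         + ηᵀΩ⁻¹η + log det 2πΩ
```

is minimized over η (damped Newton from η = 0, batched central finite
differences with step 1e-4; convergence judged on the Newton-step length,
tolerance 1e-8, because the finite-difference gradient carries O(h²) noise),
and the objective is

```
OFV = Σ_i [ L_i(η̂_i) − d·log 2π + log det (H_i/2) ],
```

`H_i` the Hessian of `L_i` at the mode.  With no random effects (d = 0) this
is the exact −2 log-likelihood.  Against 31-node adaptive Gauss–Hermite
quadrature on one-dimensional problems the approximation is accurate to well
under 0.5%.

The outer problem (typical values, Ω, β, σ) is solved by L-BFGS-B on an
unconstrained reparameterization: log for positive scalars, logit for `M_e`,
log-SD for a diagonal Ω (log-Cholesky when a full Ω is requested), raw β.
Inner solutions are warm-started per subject between outer iterations.  The
best iterate is tracked, so the reported OFV never exceeds the OFV at the
initial values.

### Covariate inclusion

Forward inclusion: a candidate effect is refit with its β free and accepted
when ΔOFV > 3.84 (χ², 1 df, α = 0.05).  The decision object also reports the
change in the random-effect variance of the parameter the covariate acts on
(the "explained variability" criterion), or `None` when that parameter
carries no random effect.

### Identifiability of the recovery study

The simulation-based recovery study (200 neonates × 4 samples, σ = 0.10)
uses a sampling schedule with the first sample at 8–16 h and subsequent
samples ~36 h apart (minimum 8 h), covering both the early
production-elevated phase and the late maturation phase, and estimates
`B0, P_ss, K_ss, M_e`, the three random-effect SDs, σ and the three
covariate effects, with the maturation time-course (`A_p, T_p, T_e`) fixed
at its known values — the analogue of fixing literature maturation functions
in a real analysis.  With all seven fixed effects free the problem is not
identifiable at this data density: fits reach a *lower* OFV than the truth
(the Laplace approximation error at 4 observations/subject is itself
O(1/n_i) and the optimizer migrates to regions where it is most favorable)
with `T_e`, `K_ss` and `A_p` trading off by 30% and more, strongly
seed-dependent.  The full-free configuration remains available through
`FitConfig` for richer designs.

## Empirical-Bayes (MAP) prediction

For a new neonate the trained model is the prior; the same `L(η)` is
minimized over η (Empirical Bayesian Estimation).  With no measurements the
mode is η = 0, i.e. the covariate-typical prediction.  The posterior is
near-quadratic at routine data densities (1–4 measurements, ≤3 random
effects), so a single Newton start suffices; jittered multi-start is
available.  The individual trajectory is then solved from birth and read out
on a 0.5 h grid (configurable) from the anchor (PNA of the last measurement
used) to the anchor + horizon.

## Validation framework

Scenarios mirror clinical questions: S1 — one measurement, predict up to
24 h past it; S2a — two measurements, up to 48 h past the second; S2b — two
or more measurements, up to 48 h past the last; stress variants extend the
horizons to 30/60 h.  Input rules (PNA in hours): first input in [8, 72],
later inputs in [24, 96], successive spacing ≥ 8; intervals closed, evaluated
on real-valued hours without rounding.  Case construction for S2 steps
backward from the last measurement until the target is within the horizon of
the second measurement; S2a then deletes intermediate measurements, S2b keeps
them.  Records that fail any rule are filtered (counted, logged), not errors.

Metrics per scenario: absolute prediction difference `p.d. = |Bpred − Bobs|`,
relative difference `r.p.d. = p.d./Bobs·100`, and a Bland–Altman acceptance
range on the signed differences, `[MW − 1.6449·SD, MW + 1.6449·SD]`
(90% limits of agreement; sample SD with n−1 — the Bland–Altman convention).
The range is computed per scenario dataset from that scenario's own
differences.

Classification against the 250 µmol/l phototherapy threshold (strict:
hyperbilirubinemia iff observed > 250): concordant cases are TP/TN;
discordant cases whose difference lies inside the acceptance range are
accepted TP/TN; discordant cases outside the range are FN/FP.  We generalize
the FN ("below the lower limit") and FP ("above the upper limit") conditions
to "outside the range" so the six categories partition every input — for an
FN the difference is necessarily negative, so the two readings differ only
when the whole range lies on one side of zero.  Sensitivity counts accepted
true positives in both numerator and denominator; an empty class yields an
undefined (None) measure, never 0.

## Synthetic cohorts

No clinical data ship with the package; cohorts are simulated to emulate a
perinatal-center validation dataset:

* Gestational age: truncated skew-normal on [168, 296] d calibrated so the
  truncated quartiles are 254/268/279 d (36+2 / 38+2 / 39+6).
* Birth weight | GA: linear growth relation (≈180 g/week) centered at
  3,085 g at the median GA, residual SD 400 g, clipped to [400, 6000] g.
* Delivery mode: cesarean with probability 620/1101.
* Measurements per neonate: truncated geometric on {1..10} calibrated to a
  mean of 2.8; first sample uniform on 10–60 h PNA, later gaps
  8 h + Exp(16 h).
* Observations: true individual trajectory × (1 + σε), floored at 1 µmol/l.

Quantiles use linear interpolation (type 7).  The generator returns the
hidden per-neonate true parameters separately for recovery tests.  The GA
truncation window is a design knob: the noise-free pipeline checks stack an
unselected cohort with a preterm stratum (GA 170–215 d) so that both sides of
the 250 µmol/l threshold are deterministically populated.

What the synthetic cohorts do **not** emulate: phototherapy intervention and
rebound, hemolytic subpopulations (blood-group incompatibility, G6PD
deficiency), transcutaneous measurements, informative sampling (real
measurement times are driven by clinical suspicion, ours are not), and any
center-specific assay bias.  Passing validation on these cohorts therefore
demonstrates internal consistency of the estimation/prediction/metric
pipeline under realistic data density and noise — not clinical performance,
which only external validation on real cohorts can establish.

## Numerical choices and problem sizes

* Trajectory quadrature: 20-point Gauss–Legendre, panels ≤ 24 h.
* Inner MAP: Newton step tolerance 1e-8, FD step 1e-4, ≤100 iterations,
  Levenberg damping when the FD Hessian is not positive definite.
* Outer fit: L-BFGS-B, gradient eps 1e-5, gtol 1e-6, ≤500 iterations.
* Degenerate inputs: empty measurement lists are valid for prediction (prior
  mode) but rejected in fitting; measurements at PNA ≤ 0 are rejected;
  acceptance ranges require ≥2 differences.
* Default test/validation problem sizes: cohorts of 200–400 neonates for
  pipeline checks, 2,000 for distributional checks of the generator, 200×4
  for the recovery study — sizes at which the checks are statistically
  meaningful while the full suite stays fast on a single CPU.

## Units

All internal computation is in µmol/l.  mg/dl is accepted and produced at
the I/O boundary with the standard conversion 17.1 µmol/l per mg/dl.  The
clinical threshold is kept at the literal 250 µmol/l regardless of unit
preference.
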