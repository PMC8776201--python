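# Methods

## The two candidate model structures

Both models describe whole-body glucose homeostasis in a diabetic mouse
with three shared channels — insulin concentration *I* (mIU/mL), blood
glucose *GL* (mg/dL) and growth hormone *GH* (mIU/mL) — over time in
minutes. They share the glucose balance

    dGL/dt = a − (b + c·I)·GL + c·GH

(hepatic production *a*, insulin-independent clearance *b*, insulin-driven
uptake *c·I·GL*, growth-hormone input *c·GH*) and the linear growth-hormone
equation dGH/dt = ρ − w·GH. The same constant *c* deliberately multiplies
both the uptake and the GH-input terms; it is implemented as a single
parameter and not split, so the equations are exactly the printed form of
the source models. The two structures differ in how insulin arises:

* **Model 1 (no β-cells, type 1 diabetes)** — insulin comes only from a
  constant subcutaneous bolus I0 absorbed at rate ψ and cleared at rate δ:
  dI/dt = ψ·I0·I/(1+I) − δ·I. Its fixed point is closed-form
  (I\* = max(0, ψ·I0/δ − 1), GH\* = ρ/w, GL\* = (a + c·GH\*)/(b + c·I\*)) and
  serves as a root-check oracle for both the algebra and the integrator.
* **Model 2 (with β-cells)** — a β-cell mass β (mg; the unit is carried as
  conventionally tabulated) grows or dies through the glucose tolerance
  window dβ/dt = (h·GL − i·GL² − g)·β and secretes insulin sigmoidally,
  dI/dt = β·d·GL²/(e+GL²) − f·I.

With w ≈ 2000 min⁻¹ against glucose dynamics of order 0.1 min⁻¹ the
systems are stiff. Integration uses LSODA (which switches to BDF on stiff
intervals) at rtol = atol = 1e-8; observation times need not coincide with
solver steps. States are never clipped inside the integrator; a solution
that becomes non-finite or falls below −1e-6 raises `IntegrationError`,
which calibration maps onto an infinite cost. Tiny negative excursions are
clipped to zero only for reporting. Solver fidelity is checked against the
exact GH solution ρ/w + (GH0 − ρ/w)·e^(−w·t) and by self-convergence under
tolerance halving.

## Synthetic virtual-mouse data

Real calibration targets of this kind are short series of group-mean blood
glucose. The generator runs the assumed data-generating process forwards:
a deterministic trajectory observed at the default grid
{0, 30, 60, 90, 120, 180, 210} min — the clinically significant
post-prandial monitoring times plus one interior point — with i.i.d.
additive Gaussian noise. Noise SD defaults to 10 mg/dL (roughly 5–10% of
normal glucose, a plausible assay scale); observations are truncated below
at 1 mg/dL rather than rejection-sampled, with truncation events logged
because they slightly bias the noise model when active.

Four frozen presets emulate severity regimes seen in experimental mouse
groups, all generated from Model 1 with parameters tuned once inside
literature-scale ranges until the target bands held, then frozen:

| profile | band (noiseless) | mechanism |
|---|---|---|
| hyperglycaemic | peak 350–450 mg/dL, then decline | low initial insulin lets glucose surge; the slowly absorbed bolus brings it down |
| hypoglycaemic | dip < 70 mg/dL, recovery into 70–200 | excess initial insulin; recovery as it clears |
| moderate | maximum 200–260 mg/dL | as hyperglycaemic, smaller production/uptake imbalance |
| controlled | entirely within 70–200 mg/dL | near-balanced production and clearance |

The generator emulates group means only: it has no per-animal hierarchy,
no dosing arms, and no non-Gaussian or heteroscedastic error. Passing
tests therefore demonstrate correctness of the machinery under the assumed
error model, not robustness to features of real assay data that violate it.
At the hyperglycaemic preset the scaled sensitivities of GL to δ and ψ are
large (order 100 mg/dL per log-unit) and non-collinear, so both parameters
are identifiable from seven noisy points — a property confirmed before the
preset was frozen.

## Calibration

Observations enter through the sum of squares SS(θ) = Σ (yⱼ − GL(tⱼ; θ))².
Each varied parameter carries a uniform prior on a bound box (defaults
bracket literature-scale estimates by roughly a factor of ten: δ ∈ [1e-3, 1],
ψ ∈ [1e-2, 1e2], a ∈ [1, 1e3], b ∈ [1e-3, 5], f ∈ [1e-2, 1e3],
i ∈ [1e-8, 1e-4]); the error precision σ⁻² carries a conjugate
Gamma(n0/2, n0·S0/2) prior so that its full conditional
Gamma((n0+n)/2, (n0·S0 + SS(θ))/2) can be sampled exactly at every MCMC
step. Defaults n0 = 1 and S0 = SS(θ̂_LS)/n (the least-squares variance
estimate) are weakly informative.

The default varied sets are {δ, ψ} (k = 2) for Model 1 and {a, b, f, i}
(k = 4) for Model 2; all other parameters stay fixed. Fitting proceeds as:

1. **Least squares** — the cost surface has narrow basins surrounded by
   nearly flat plateaus (a poor start leaves a local solver stranded), so
   the box is first probed at ~16·d log-uniform points ranked by SS;
   trust-region-reflective solves then run from the best-ranked starts and
   the geometric midpoint, keeping the overall best. Integration failures
   return large residuals instead of raising.
2. **DRAM** — a Metropolis chain started at θ̂_LS with initial proposal
   covariance σ̂²(JᵀJ)⁻¹ from the Gauss–Newton curvature (marginals capped
   at 1/50 of the box width so a flat direction cannot blow up the
   proposal). The covariance is re-estimated from the chain history every
   100 iterations after iteration 1,000, scaled by 2.4²/d. A rejected
   proposal gets one delayed-rejection retry at 1/5 scale using the
   two-stage acceptance probability that preserves detailed balance.
   When σ² is unknown, θ moves are accepted under the σ²-marginalised
   likelihood (n0·S0 + SS(θ))^(−(n0+n)/2) and σ² is drawn each iteration
   from its conjugate full conditional for recording and prediction; this
   targets the same joint posterior as alternating conditional updates but
   avoids a severe mixing pathology of the uncollapsed scheme, in which σ²
   inflates to accommodate any badly fitting state and excursions onto
   high-SS plateaus become near-absorbing. With σ² held fixed the
   acceptance uses the plain Gaussian kernel exp(−0.5·ΔSS/σ²), which is
   how the sampler is validated against closed-form Gaussian and
   Student-t posteriors. If more than half of the in-box proposals fail
   to integrate, the sampler aborts with diagnostics.
3. **Summaries** — posterior medians with 95% credible intervals as the
   2.5%/97.5% quantiles of the post-burn-in chain (burn-in fraction 0.5,
   conservative for short adaptive chains). Convergence is reported
   quantitatively: autocorrelation-adjusted effective sample size and a
   stationarity z-score comparing the first 10% against the last 50% of
   the chain; ESS < 200 or |z| > 2 raises a flag recommending an extended
   run.

The default chain length is 100,000 iterations. Test and acceptance runs
use 3,000-iteration chains for the two-parameter Model 1 posterior and
800–2,000 for Model 2 — sizes chosen from mixing diagnostics (ESS ≈ 400 at
3,000 iterations with least-squares initialisation). Posteriors with long
correlated ridges (which arise for some noise realisations, since δ and ψ
enter partly through their ratio) mix slowly and are exactly the cases the
extension flag is designed to catch.

## Model selection

Under the Gaussian error model the maximized likelihood is a function of
the minimized SS alone, so both criteria are computed on the profile scale

    AIC = n·ln(SS/n) + 2k        BIC = k·ln(n) + n·ln(SS/n)

with SS the best value found across the least-squares fit and the chain
(both criteria are defined at the maximized likelihood, and this choice
makes the IC input deterministic given the chain). A `likelihood` mode adds
the constant n(ln 2π + 1) to both; model differences are identical in both
modes, and the identity AIC − BIC = 2k − k·ln n holds by construction.
Structures are compared through Δ = IC(Model 2) − IC(Model 1) with the
conventional evidence threshold of 2: the verdict is "substantial
difference" only when both |ΔAIC| and |ΔBIC| reach 2, otherwise
"equally capable".

## Pipeline

`run_pipeline` fits both models to every dataset (file or presets),
persists datasets, chains, summaries and diagnostics as delimited text,
writes a selection report mirroring the per-dataset AIC/BIC table, and
renders each fit with its pointwise 95% credible band. Bands are built by
thinning the post-burn-in chain to ≥ 500 draws, simulating GL per draw, and
taking per-time quantiles; observation noise drawn from the sampled σ² can
be added for a posterior-predictive band. A run log records seeds, bounds,
chain lengths, acceptance rates, ESS and the IC mode, sufficient to
reproduce a run byte-for-byte. For preset data, Model 1's non-varied
parameters are fixed at the generating values (the "known biology"
convention); file datasets fall back to literature-scale baselines
(a = 45 mg/dL·min, b = 0.13 min⁻¹), both user-overridable.

## Numerical choices and degenerate inputs

* Out-of-box parameters and integration failures cost +∞ (zero posterior
  mass); the least-squares path substitutes large finite residuals instead.
* SS = 0 makes the information criteria undefined on the log scale and is
  signalled rather than returned as −∞.
* A Gamma posterior with zero rate (n0·S0 + SS = 0) is signalled.
* Glucose observations are strictly positive by construction (1 mg/dL
  floor); datasets violating this are rejected on load.
* Proposal covariances are Cholesky-factorised with escalating jitter; a
  degenerate chain history keeps the previous proposal rather than failing.

## Known limitations

* Only the glucose channel is fitted; insulin and growth-hormone data, if
  available, are unused (single-channel likelihood).
* The synthetic generator's truncation floor slightly biases the error
  model when noise is extreme relative to the trajectory.
* Severity presets are frozen configurations, not estimates of any real
  mouse group; quantitative agreement with any published table is not
  expected, and conclusions from the package are about method behaviour
  under its own assumptions.
* No prior elicitation or posterior-robustness analysis is provided; the
  uniform-box and conjugate-Gamma priors are fixed conventions.
* No meal/bolus event handling: insulin enters only through the constant
  bolus term.
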