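# Methods

This note documents the models, the numerical choices, the synthetic-data
generator, and the limitations a user should know before trusting results on
real cohorts. Times are days inside the survival machinery; sojourn rates
are per year and conversions use 365.25 days/year.

## Survival core

**Cox engine.** `fit_cox` maximises the partial likelihood by
Newton–Raphson with step-halving (the accepted likelihood path is
monotone), Efron tie handling by default (day-resolution follow-up data are
heavily tied) and Breslow by flag; with no ties the two coincide and this is
asserted in tests. Convergence is declared at max|score| < 1e-8 within 50
iterations; on large cohorts the score can stall at the float64 accumulation
floor of the cumulative risk-set sums, in which case the fit is accepted
when the likelihood is stationary and the score is below 1e-6 of its initial
magnitude, and the fit carries an explanatory flag. Rank deficiency is
detected up front by QR and reported with the suspect columns; monotone
likelihoods (perfect separation, |β| > 10) are flagged as non-converged
rather than silently returned — the screened-subcohort situation in which a
factor level has no events surfaces this way instead of being guessed
around. Wald CIs and p-values are reported; all risk-set quantities are
computed with reverse cumulative sums and per-tie-group scalar weights, so
a refit costs O(np²) per iteration with no Python loop over event times —
the Monte Carlo grid and the frailty profile rely on this, plus warm starts.
Inference is cross-checked in the test suite against an independent
implementation (lifelines) and, on all ≤10-subject fixtures, against direct
numerical maximisation of the explicitly written partial likelihood
(agreement to 1e-6 in β).

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
Greenwood variances and plain ±1.96·SE confidence bands are derived from
the event table, the median is the smallest time with S(t) ≤ 0.5 (NaN if
never reached).

**Proportional-hazards check.** Scaled Schoenfeld residuals
(s* = d·V⁻¹·s + β̂) with the Grambsch–Therneau score test against the
identity time transform; a covariate is declared non-violating at p ≥ 0.05.
With fewer than 3 events the test is undefined and flagged. Under a
well-specified model the per-covariate flag rate is ~5% (checked by
simulation); a sign-reversing effect is detected with high probability.

## Shared gamma frailty

Patients in cluster j (region of residence) share a multiplicative frailty
w_j ~ Gamma(1/ξ, 1/ξ) (unit mean, variance ξ). For fixed ξ the model is
fitted as a penalized partial likelihood in (β, b) with b_j = log w_j and
penalty (1/ξ)Σ(b_j − e^{b_j}); the stationarity condition reproduces the
classical EM fixed point e^{b_j} = (1/ξ + D_j)/(1/ξ + Λ_j) (D_j events,
Λ_j cumulative hazard of the cluster), but Newton steps converge
quadratically where the EM alternation is painfully linear. The frailty
variance is then profiled over [0, 5] on the closed-form marginal
log-likelihood obtained by integrating the frailties out against the
Breslow baseline. On tiny fixtures the profiled fit agrees to 1e-4 with
brute-force maximisation of that marginal likelihood over (β, baseline
increments), and ξ = 0 reduces exactly to the plain Cox fit.

**Presence test.** 2·(ll_marginal(ξ̂) − ll_marginal(0)) referred to the
50:50 mixture of χ²(0) and χ²(1) (the ξ = 0 null sits on the parameter
boundary). *Known limitation:* in simulations under ξ = 0 the statistic is
stochastically smaller than the mixture — P(ξ̂ > 0) ≈ 0.32–0.39 rather than
0.5 — because the profiled baseline absorbs part of the between-cluster
variation; the realised size is ~2–4% at nominal 5% across cluster designs
from 6×500 to 40×30, and censoring increases the conservatism. The test
therefore controls its size but under-rejects; its power is nonetheless
high (≈85% at ξ = 0.5 with two clusters of 500). Reported coefficient
standard errors condition on ξ̂ and ignore its sampling uncertainty. With
fewer than 5 clusters ξ is weakly identified; the fitter warns and runs,
since the motivating design has exactly two regions.

## Lead-time correction

Fixed variant: screened cases lose 100 days (stages I–II) or 30 days
(III–IV). Sojourn variant: E(s) = (1 − e^{−λt})/λ subtracted per screened
case, events and censored alike; corrected times are floored at 1 day and
the floor count reported, preserving records rather than deleting them.
λ is per year; the grid 0.05–1.0 therefore spans mean sojourn times of 1–20
years, and normal draws are truncated below at 1e-6 because an untruncated
normal admits negative rates. One λ is drawn per screened case per
replicate by default (a per-replicate single draw is available by flag).
Monitored p-values are Wald. Grid cells seed independent generators derived
from (seed, cell indices), so results are bit-reproducible and invariant to
record order; non-convergent refits are counted per cell, never dropped
silently.

*Known limitation (established by simulation against the generator's truth
table):* subtracting the conditional expectation E(s|t) corrects the mean
of the observed screened survival but not its shape. When recorded survival
is genuinely lead + post-symptomatic survival, the screened group retains
an early-time hazard deficit that no deterministic per-record shift can
repair; at λ = 0.45/yr with survival scales calibrated to the study, the
residual log-HR bias is ≈ −0.13 (the correction removes ~80% of the
lead-time bias; subtracting the *realised* lead times removes it entirely
and restores nominal CI coverage). Conclusions of "bias removed" based on
this correction are therefore conservative in the direction of retaining
part of the spurious benefit.

## Length-bias correction

Single-parameter subtype model (θ scales both the non-aggressive fatality
and the aggressive screen-detection probability — the reading under which
"k times more screen-detectable and k times less lethal" is one claim).
Given (p1, p2, p3) and (q, θ):

* s = p3 / (qθ + 1 − q) — non-aggressive screen-detection probability;
* δ = p1 (A + B) / (A + Bθ) with A = q(1 − θs), B = (1 − q)(1 − s) —
  aggressive symptomatic 5-year fatality;
* Ψ solves p2 = [qθ(1 − (1 − δ)^Ψ) + (1 − q)(1 − (1 − θδ)^Ψ)]/(qθ + 1 − q)
  by Brent root-finding on (1e-6, 10]; values above 10 get a distinct
  no-solution code. φ = p2(qθ + 1 − q)/(θδ) is the risk-scale analogue, and
  a risk-scale Ψ variant is available by flag.

Cells where s or δ leaves (0, 1] or no root exists are explicit no-solution
markers — the blank region of the surface. Every returned solution is
back-substituted into all three observed quantities and must reproduce them
to 1e-8; this guards the reconstructed mixture algebra. Ψ is monotone
non-increasing in θ along fixed-q transects (weaker assumed bias leaves
more of the advantage standing; θ = 1 returns the uncorrected ratio), and
the nullification factor searches the largest θ admitting Ψ = 1 by
bisection (tolerance 1e-4) with an inner grid-plus-refinement maximisation
over q. The solver is validated generatively: cohorts simulated at known
(q, θ, Ψ*) return Ψ̂ within Monte Carlo error of Ψ* when solved at the true
(q, θ).

Crude case fatality (deaths within the horizon / group size) is used for
p1/p2 to mirror the published arithmetic; with censoring before the horizon
this underestimates fatality, so a Kaplan–Meier variant is provided and the
discrepancy is asserted in tests. Lead-time and length-bias corrections are
treated separately, as in the source analysis; their interaction is out of
scope.

## Unmeasured-confounder adjustment

Array-approach external adjustment: HR_adj = HR_obs × [p0γ + (1 − p0)] /
[p1γ + (1 − p1)] for a binary confounder with hazard ratio γ and
prevalences p1 (exposed) / p0 (unexposed); CI limits scale by the same
factor. Prevalences are mandatory explicit inputs — no defaults are
published to copy. The adjustment is multiplicative and inverts under
prevalence swap at the same γ (note: *not* under γ → 1/γ at swapped
prevalences, a symmetry that does not hold for this factor).

## Synthetic cohort generator

The generator is the testbed for every correction; its defaults are the
study's structure where published, and calibrated or chosen once otherwise:

| parameter | default | origin |
| --- | --- | --- |
| n | 3405 | analysed cohort size |
| XF fraction | 0.204 | published regional share |
| screen prob (XF / non-XF) | 0.176 / 0.053 | published screened fractions |
| sojourn rate λ | 0.45/yr | 1/2.24-year mean sojourn (Mayo Lung Project figure cited by the study) |
| aggressive fraction q | 0.9 | chosen: lung cancer has a small indolent fraction |
| subtype factor θ | 0.5 | chosen: moderate length-bias differential |
| true screening effect Ψ* | 1.0 | null — the working hypothesis the bias analyses test |
| baseline hazard | 0.135/yr | calibrated: unscreened non-XF median survival ≈ 469 d vs published 463 d |
| censoring rate | 0.30/yr | calibrated: crude symptomatic 5-y fatality ≈ 0.59 vs published 0.58 |
| covariate log-HRs | published multivariate estimates (age > 65, sex, stage, surgery, region) | realistic effect sizes |
| frailty variance ξ | 0 | null; the published heterogeneity scale is not recoverable |

Mechanism: subtype is drawn first; screen detection uses s_r =
p_region/(qθ + 1 − q) for the non-aggressive subtype and θ·s_r for the
aggressive one, so regional screened fractions hit their targets while the
screened group is enriched for the indolent subtype — exactly the mixture
the length-bias solver inverts. Post-symptomatic survival is exponential
with hazard baseline × exp(βx) × frailty; the non-aggressive hazard is set
so its within-horizon fatality is θ × the aggressive one; Ψ* multiplies the
within-subtype hazard of screened cases. Screened cases record lead + 
post-symptomatic survival, with the lead an Exp(λ) residual sojourn
(memorylessness). Censoring is exponential and independent — the study's
administrative censoring pattern, its 11.7% failed telephone follow-up, and
calendar-time screening rollout are deliberately not modelled. Stage,
demographics and treatments are drawn from distributions matched to the
published stratified table margins; only the covariates listed above affect
the hazard. Everything is a pure function of (config, seed).

What passing tests therefore show: the estimators and corrections are
correct *under the generator's assumptions* (exponential survival and
sojourn, multiplicative effects, independent censoring). Real cohorts
violate several of these (non-exponential survival above all), and the
corrections inherit the source methods' reliance on them.

## Problem sizes used in the validation suite

Round-trip recovery of Ψ uses 27 factorial cells × 4 cohorts of 200,000
(per-cell Monte Carlo SE ≈ 0.003 against the 0.02 acceptance bound); the
lead-time study uses 200 seeded cohorts of 5,000; Cox CI coverage uses 200
replicates of 2,000; frailty size/power use 500 null and 200 alternative
replicates; the Monte Carlo grid check runs the full 20 × 20 grid at 100
replicates on a 400-patient cohort. The analysis drivers default to a
10 × 10 grid at 50 replicates; the full 0.05-step, 1000-replicate
configuration runs through the same interfaces.
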