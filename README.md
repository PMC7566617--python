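# screenbias

Screening-bias-aware survival analysis for retrospective cancer cohorts.

When part of a cohort was diagnosed by screening, naive survival comparisons
are contaminated by **lead-time bias** (screening advances the date of
diagnosis without necessarily postponing death, inflating observed survival)
and **length bias** (slowly progressing, less lethal tumours spend longer in
the preclinical screen-detectable phase and are over-represented among
screen-detected cases). This package implements the survival machinery and
the bias-correction methods used to analyse overall survival in a lung-cancer
cohort from Yunnan, China, in which residents of the coal-pollution-exposed
Xuanwei–Fuyuan (XF) counties were screened far more intensively (17.6% of XF
cases screen-detected vs 5.3% elsewhere), together with a calibrated
synthetic-cohort generator so that every correction can be validated by
parameter recovery without any patient-level data.

It is aimed at epidemiologists and biostatisticians analysing observational
cohorts with differential screening uptake.

## What is inside

| Module | Contents |
| --- | --- |
| `screenbias.cohort` | patient-level data model, CSV I/O, region × screening stratified summaries |
| `screenbias.survival` | Kaplan–Meier + Greenwood CIs, log-rank test, a fast Cox partial-likelihood engine (Newton–Raphson, Efron/Breslow ties, step-halving, offsets, warm starts), scaled Schoenfeld residuals with the Grambsch–Therneau test |
| `screenbias.frailty` | shared gamma frailty Cox model (region as cluster), profiled marginal likelihood, boundary-mixture LRT for frailty presence |
| `screenbias.leadtime` | fixed stage-based correction (−100 d stages I–II, −30 d III–IV); exponential-sojourn correction E(s) = (1 − e^(−λt))/λ; Monte Carlo grid over (mean λ, SD λ) with repeated Cox refits |
| `screenbias.lengthbias` | two-subtype length-bias model: corrected relative hazard Ψ and risk φ over a (q, θ) surface, and the nullification factor 1/θ* |
| `screenbias.confounder` | external adjustment of an observed HR for an unmeasured binary confounder |
| `screenbias.simulate` | synthetic cohort generator (regional screening differential, exponential sojourn, non-aggressive subtype, covariate effects, frailty, censoring) plus hidden truth tables |
| `screenbias.pipeline`, `screenbias.cli` | end-to-end orchestration and the `screenbias` command line |

Numbered drivers under `analysis/` run the full story on a synthetic cohort
(`01_simulate_cohort.py` … `06_confounder_sensitivity.py`) and write their
tables under `results/`.

## The core corrections

**Lead time.** For a screen-detected case observed for `t` years, assuming an
exponentially distributed preclinical sojourn with transition rate λ (mean
sojourn 1/λ years), the expected lead time is

    E(s) = (1 − exp(−λ t)) / λ,

which is subtracted from the observed time (floored at 1 day). The Monte
Carlo grid draws one λ per screened case from Normal(mean, SD), corrects,
refits the Cox model, and repeats, mapping the fraction of replicates with
p > 0.05 and the hazard-ratio range for screening and region over the grid
0.05–1.0 per year on both axes.

**Length bias.** A non-aggressive subtype with proportion 1 − q is assumed to
be 1/θ times as likely to be screen-detected and θ times as likely to kill
within 5 years as the aggressive subtype (θ ∈ (0, 1]). From the observed
crude inputs — p1 (5-year case fatality of symptomatic cases), p2 (same for
screen-detected), p3 (screened fraction) — the solver recovers the subtype
parameters (s, δ) and the within-subtype relative hazard Ψ of screen-detected
vs symptomatic cases net of length bias, under exponential survival
(fatality p maps to 1 − (1 − p)^Ψ). θ = 1 collapses Ψ to the uncorrected
ratio ln(1 − p2)/ln(1 − p1). The **nullification factor** is the smallest
fold-difference 1/θ at which some subtype mix q makes Ψ = 1, i.e. at which
length bias alone could explain the whole observed advantage.

**Shared frailty.** Patients in a region share a multiplicative gamma
frailty with unit mean and variance ξ; ξ is profiled by maximising the
closed-form gamma-marginal likelihood (fitted as a penalized partial
likelihood), and frailty presence is tested against the 50:50
χ²(0)/χ²(1) boundary mixture.

## Worked example

```python
from screenbias import (ObservedFatalities, nullification_factor,
                        uncorrected_relative_hazard)

# published crude inputs: 1829/3148, 57/270, 270/3415
obs = ObservedFatalities(p1=0.58, p2=0.21, p3=0.079)
print(round(uncorrected_relative_hazard(obs), 4))   # 0.2717
res = nullification_factor(obs)
print(round(res.k, 2), round(res.theta_star, 3))    # 8.37 0.119
```

The uncorrected relative hazard 0.27 says screen-detected cases die at about
a quarter of the symptomatic rate; the nullification factor says a
length-bias subtype would need to be ~8× more screen-detectable **and** ~8×
less lethal before that advantage could be an artefact of length bias alone —
implausible for lung cancer, whose mean sojourn is short.

On a synthetic null cohort (no true screening benefit, sojourn rate
0.45/yr), `analysis/03_survival_models.py` and `analysis/04_lead_time.py`
print, for one seed:

```
Cox screened: HR=0.505 (0.382-0.669), p=1.85e-06       # spurious benefit
fixed 100/30-day correction: screening HR=0.539 (0.407-0.713)
Monte Carlo grid (10x10 cells x 50 replicates):
  max P(p>0.05) for screening: 1.0000                  # null recovered
```

— the naive model manufactures a strong protective effect out of pure lead
time, and the sojourn correction at the generative rate removes it.

Command-line equivalents:

```bash
screenbias simulate --n 3405 --seed 1 --out cohort.csv
screenbias summarize --input cohort.csv --out summary.json
screenbias lengthbias --p1 0.58 --p2 0.21 --p3 0.079 --out surface.csv
screenbias run --config pipeline.yaml
```

## Limitations

See `docs/methods.md` for the model assumptions, the generator calibration,
the known finite-sample conservatism of the frailty presence test, and the
structural residual bias of expectation-based lead-time correction.
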