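# geodebut

Geoadditive survival analysis of age at sexual debut: censored
time-to-event records with cluster point locations and survey weights,
fitted through a Poisson-offset approximation of the Cox proportional
hazards model whose spatial smooth is a low-rank kriging spline.

## The problem

National household surveys of adolescents and young adults (15–24)
record, for each respondent, the age at first sexual intercourse — or,
for those who have not yet debuted, the current age as a right-censoring
time.  Respondents are sampled in enumeration-area clusters that share
one geographic coordinate, and carry inverse-probability survey weights.
Public-health questions attach both to the covariate effects (does
alcohol use, residence, or sex shift the hazard of early debut?) and to
the *spatial* pattern of risk that measured covariates do not explain.

This package implements that analysis end to end for epidemiologists and
biostatisticians working with such survey data:

1. **Descriptives** — Kaplan–Meier curves, log-rank tests, and
   early-debut (< 15 years) prevalence tables with survey-weighted
   percentages and Pearson chi-square tests.
2. **Cox model** — survey-weighted partial likelihood with Breslow tie
   handling and the Breslow cumulative baseline hazard Λ̂₀.
3. **Poisson reduction** — with the counting process evaluated at
   t = ∞, each record contributes a Poisson cell N_i = δ_i with known
   offset log Λ̂₀(t_i), turning the censored-data problem into a
   generalized linear model with no intercept.
4. **Geoadditive mixed model** — the linear predictor gains a bivariate
   smooth of location, S(s) = s′β_s + Σ_k u_k z_k(s), with radial basis
   Z = C(s,κ) C(κ,κ)^(−1/2) built from one of six covariance families
   (exponential, Gaussian, Matérn 3/2, spherical, circular, inverse
   quadratic), knots placed by a space-filling maximin rule with
   K = max{20, min(n/4, 150)}, u ~ N(0, σ²ᵤI), fitted by penalized
   quasi-likelihood; the range τ is profiled on the working model's
   restricted likelihood and the family chosen by AICc (BIC tiebreak).
5. **Mapping** — the fitted spatial log hazard-ratio surface on a grid,
   exported as CSV/GeoJSON.

A synthetic-cohort generator with known covariate effects and a known
smooth spatial field stands in for restricted survey microdata, so every
stage is testable.

## Worked example

The `analysis/` scripts run the full study on the calibrated synthetic
cohort (n = 5,000 in 250 clusters; integer-year ages; survey weights):

```bash
python analysis/01_simulate.py
python analysis/02_descriptives.py
python analysis/03_cox_offset.py
python analysis/04_geoadditive_fit.py
python analysis/05_map_surface.py
```

`01_simulate.py` prints the generator's calibration facts:

```
cohort: n=5000 over 250 clusters
early debut (<15y) fraction: 0.190
KM median debut age: 16.0 years
event fraction: 0.874
```

i.e. 19.0% of the cohort debuts before age 15 and the median debut age
is 16 — the regime typical of southern-African surveys of this age
group.  `03_cox_offset.py` fits the weighted Cox model and verifies the
Poisson reduction:

```
            term     beta       se       HR   CI_low  CI_high
       sex[male] 0.115222 0.030403 1.122123 1.057210 1.191021
residence[rural] 0.112823 0.030535 1.119434 1.054404 1.188475
    alcohol[yes] 0.265738 0.039439 1.304393 1.207363 1.409221

Poisson-offset refit vs Cox: max |delta beta| = 1.05e-15
```

The refit agreement is exact to machine precision: with Breslow offsets
the Poisson score coincides with the partial-likelihood score.  Note the
hazard ratios sit below the generator's true values (1.25, 1.15, 1.5) —
integer-year reporting produces heavy ties, and the Breslow partial
likelihood then targets a slightly attenuated discrete-time estimand
(see `docs/methods.md`).  `04_geoadditive_fit.py` compares the six
covariance families and prints the adjusted hazard ratios of the
geoadditive model (overall and stratified by sex); on this cohort the
smooth families rank at the top and the overall alcohol aHR is
1.33 (1.23–1.43).  `05_map_surface.py` checks the fitted spatial surface
against the generator's known two-bump field:

```
surface recovery: Pearson r = 0.971 over 9344 grid points
```

The same pipeline runs from the command line on any conforming CSV:

```bash
geodebut run-all --config configs/default_run.yaml --seed 11 --out results/run
```

Outputs: `table1.csv`, `km_curves.csv`, `logrank.csv`, `cox_fit.csv`,
`baseline_cumhaz.csv`, `family_comparison.csv`, `hr_{overall,female,male}.csv`,
`surface_*.csv/.geojson`, and a `manifest.yaml` with seeds, versions and
stage timings.  Re-running with the same config and seed reproduces
every numeric output byte for byte.

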