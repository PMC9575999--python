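# Methods

This note documents the model, the estimation machinery, the synthetic
study design, and the numerical and design choices behind `wildemo`.

## Hazard model

Mortality of females is a Siler competing-hazard curve,
`h(a) = a1·e^{−b1·a} + a2 + a3·e^{b3·a}` (all rates per year), covering
the declining risk of early calfhood, an age-independent floor, and
senescence.  Cumulative hazard has the closed form
`H(a) = (a1/b1)(1 − e^{−b1·a}) + a2·a + (a3/b3)(e^{b3·a} − 1)`; the
degenerate rates `b1 → 0` / `b3 → 0` are evaluated by their linear limits
so sampler moves near zero remain valid, and components with zero scale
(`a1 = 0`, `a3 = 0`) are short-circuited to avoid `0·∞` at extreme ages.

Covariates act proportionally on the hazard: a wet-season (December–May)
log-increment `β_S`, a slope `β_L` per km of distance along the migratory
axis (negative values put the extra risk at the southeastern,
low-distance end), and per-calendar-year increments `β_Y` constrained to
sum to zero so the Siler baseline stays interpretable as the across-year
mean.  `β_L` is applied to raw km; with the ~100 km separation between
the seasonal ranges its magnitude is of order 0.004/km, and the adaptive
proposal covariance absorbs the scale difference without an explicit
re-parameterization.  Covariate paths are piecewise constant at
calendar-month resolution (seasons are defined by month; locations change
on the ~monthly migration schedule), so integrating the modified hazard
is an exact sum of `exp(linear predictor)·ΔH` terms.

Calf dissociation (weaning separation) is a hazard in the same
mathematical sense, `max(0, γ_D·(a − 0.75))`, zero before 0.75 yr: the
association survival is `exp(−γ_D·(a − 0.75)²/2)` thereafter.  Linearity
in `(a − 0.75)` is the minimal form consistent with dissociation that
begins around July and is concentrated in the last quarter of the calf
year.

Longevity is the age reached by a stated fraction of females (default
0.1%), solved by bracketed bisection on the cumulative hazard to 1e−6 yr.
Life expectancy at birth is the integral of survivorship; no closed-form
antiderivative exists, so adaptive quadrature (relative tolerance 1e−10)
is taken up to the age where survivorship falls below 1e−12.

## Likelihoods

**Collared cows (CC).**  Each cow's history is left-truncated at her
tooth-estimated entry age — the record conditions on survival to entry,
since collared animals were alive at capture; ignoring this would bias
the senescent parameters.  Entry ages are treated as exact point
estimates.  A censored record contributes `−H_mod(entry → last alive)`
along its covariate path; a death adds `log(1 − e^{−ΔH})` across the
window between the last live sighting and the carcass-discovery date
(mortality sensors trigger at 12 h but discovery lags).  Windows shorter
than one day use the hazard density directly.  Cow locations between
sightings are interpolated linearly from the record's own sightings;
suspected poaching mortalities are removed entirely upstream (dropping
~2% of animals with an independent removal process perturbs the natural
hazard estimate negligibly).  Recollared animals are represented as one
history keyed by animal.

**Herd counts (HC).**  With per-cow expected surviving calves
`r = f·S_c(t)` at time `t` since the 1 October birth pulse, the expected
calf fraction among classified calves+cows is `r/(1+r)` and the calf
count is binomial.  Counts during 1 September – 31 October are excluded
(calf presence cannot be assessed near calving), as are counts with zero
classified animals.  Within-year cow mortality is ignored in the ratio (a
dying cow's calf is assumed lost with her, leaving the ratio
approximately unchanged).  The calf's covariate path follows the
canonical migration schedule; the calf hazard shares the full Siler curve
(immature component plus the adult terms) and the season modifier, so one
coherent hazard spans birth to senescence.

**Calf detections (CD).**  Per cow-year, a hidden-state forward recursion
over {no-calf-born, calf-present, calf-dead, calf-dissociated}: initial
mass `f` on calf-present at the pulse; between observations calf-present
mass decays through the modified calf-death hazard plus the dissociation
hazard; emissions are `p` for a detection with the calf present and `q`
in every calf-absent state.  Because the three calf-absent states share
one emission distribution, the forward sum collapses to a single pass
over the possible departure intervals; the vectorized implementation
computes exactly that and matches exhaustive hidden-path enumeration to
1e−10 on short sequences (tested).  All likelihoods are compiled once per
dataset into flat segment arrays so a sampler evaluation costs a handful
of vectorized operations (~0.1–0.5 ms at study scale).

## Estimation

Sampling is adaptive random-walk Metropolis on transformed scales: log
for positive rates, logit for probabilities, identity for signed effects.
During burn-in (by default the first half of each chain) the proposal
covariance is re-estimated from the chain's own history with the
`2.38/√d` scaling and a global factor is tuned toward ~28% acceptance;
both are frozen at the end of burn-in, so the retained draws target the
exact posterior.  Full-covariance adaptation replaced a per-parameter
diagonal scheme after the diagonal walk showed split-R̂ up to 2.4 on the
strongly correlated fecundity-versus-hazard posteriors at short chain
lengths.  Chains are seeded through a `SeedSequence` tree, making every
stochastic output bitwise reproducible; split-chain R̂ is reported per
parameter, and a burn-in with zero acceptances raises a diagnostic error.

Default priors are normal on the transformed scale: sd 2 on log scales
and sd 2.5 on logit/identity scales — weakly informative (a log-sd of 2
spans four orders of magnitude around 1).  A much wider log-scale prior
was rejected on statistical grounds: for a partially identified positive
parameter whose likelihood is flat below a ceiling (the constant hazard
`a2` trades off against the senescent term), the implied natural-scale
prior behaves like `1/x` over many decades, the posterior escapes toward
zero, and interval estimates degenerate.

**Stage structure.**  The fits run in sequence — CC, then the
single-effect extensions CC.S / CC.L / CC.Y (separate models, not one
joint fit), then HC, HC.Y, CD, CD.Y.  After each stage every sampled
parameter's pooled posterior is moment-matched by an independent normal
on its transformed scale and becomes the prior wherever a later stage
samples the same parameter.  Two scoping choices matter:

* the CC stages sample only the adult-relevant parameters (`a2, a3, b3`
  plus the stage's effect) — collared adults carry no immature-age
  exposure, and carrying a pure prior artifact for `a1, b1` forward had
  distorted the fecundity/first-year-survival split downstream;
* the hazard curve and `β_S` are chained across observation models, but
  fecundity (and `p, q, γ_D`) are estimated afresh by each of HC and CD,
  whose vital-rate estimates are reported side by side.  Chaining
  fecundity itself double-counts the ridge between `f` and the immature
  hazard: the moment-matched prior factorizes that ridge, drops its
  correlation, and yields overconfident combined intervals.

The moment-matching approximation is bounded by a joint-sampler oracle in
the test suite: on a shared dataset the sequential and joint posterior
means agree within ~0.2–0.35 posterior SD, with same-order spreads.
Incomplete first and last study years are excluded from the year-effect
vectors.

Posterior summaries follow the evidence-ratio convention: EV, shortest
90.9% HPD interval (90.9% = 10/11 is the level whose evidence ratio
Pr/(1−Pr) is 10), LCL0 as the `1 − level` quantile, Pr > 0, and
`LER = log10(Pr/(1−Pr))` with 0.5/1.0/1.5/2.0 read as substantial /
strong / very strong / decisive.  Derived quantities — first-year
survivorship along the seasonal path, recruitment `f·S1`, annualized
survival `e^{−h(a)}`, longevity, life expectancy, `maxR`/`meanR` of
annual hazard levels (with calf-year hazard `h1 = −ln S1` and adult-year
hazard `h_A = e^{β_Y}`) — are computed per posterior draw and summarized
the same way.

## Leslie projection

Female-only, biannual.  The state holds 51 six-month classes at nominal
ages 1.0–26.0 — "ranging from 1 to 25 years" is not self-consistent at
half-year width, so the grid extends to 26 with the oldest class
absorbing; survivorship is essentially zero beyond 16 yr, so λ is
insensitive to the cap — plus two latent juvenile slots that carry each
birth cohort to its entry into the 1-yr class.  The dry step (June–
November) contains the 1 October pulse: cows ≥ 2.0 yr contribute
`0.5·f` female newborns (yearlings zero), and the cohort born the
previous year enters the 1.0-yr class with first-year survival S1.
Class-to-class survival over a step is `exp(−m_season·ΔH)` with the
wet/dry modifier evaluated at that season's range location.  A 50-yr
warm-up with per-step renormalization converges to the stable age
distribution (verified: final annual change < 1e−6 per class, and the
result is independent of the initial vector); λ is the fifth root of the
abundance ratio over a 5-yr free projection and matches the dominant
eigenvalue of the annualized wet∘dry operator to 1e−6 (tested).
Turnover is deaths among the age-1+ classes over a year divided by
start-of-year abundance, averaged over the horizon and reported for runs
with λ in (0.98, 1.02).  Posterior projections pair independent draws
from the collared-cow (adult survival) and herd-count (fecundity, S1)
posteriors; with one annual pulse and half-year classes the stable
structure occupies alternating classes, which is the expected cohort
pattern rather than an artifact.  Density dependence is deliberately
absent.

## Synthetic study design

The generator's defaults are the study conditions: 8 study years
beginning with 45 collared cows in May of year one, 10 more each
October–December; biweekly sighting attempts with 90% success; collar
life 5 yr; ~60 scheduled herd counts per year (those in the
calving-season window are generated and then excluded by validation,
leaving ~400) with classified-sample sizes Poisson(57); a 2%/yr
suspected-poaching removal hazard; fecundity 0.68; detection p = 0.89
and q = 0.02; wet-season hazard ratio 1.27; location and year effects
zero; dissociation slope γ_D = 40/yr² (≈70% of surviving calves
dissociated by age 1).  The Siler baseline
`(a1, b1, a2, a3, b3) = (1.771, 4.0, 0.0613, 0.0167, 0.340)` was solved
once from the annual-survival anchors 0.91 at age 2, 0.57 at age 10 and
0.02 at age 16, with the immature scale set so that first-year
survivorship along the seasonal migratory path (wet-season modifier
active) is 0.56; `b1 = 4/yr` is a choice (early mortality concentrated
in the first months).  Entry ages are uniform on 2–10 yr; cows follow
the deterministic monthly migration cycle (southeast ≈ 20 km in
December–April, northwest ≈ 120 km in July–October, transits between).

Death times are drawn by inversion of the piecewise cumulative modified
hazard along that path; calf deaths and dissociation times likewise, and
herd-count calf numbers are binomial at the model's expected fraction —
so the generating process is exactly the process the likelihoods
integrate, which is what parameter-recovery testing requires.  The
generator does **not** emulate individual heterogeneity (frailty), herd
formation, collar failure clustering, aging error in the tooth-based
entry ages, or spatial variation beyond the one-dimensional axis; passing
recovery tests therefore demonstrates the correctness and calibration of
the estimation machinery under the study's design, not robustness to
model misspecification in real field data.

## Calibration at study scale

Forty simulated replicates of the default design, fitted with the
CC → CC.S → HC → CD sequence at 2 chains × 3000 steps (half burn-in),
give 90.9% HPD coverage of 35/40 (fecundity, from CD), 36/40 (S1, from
CD), 37/40 (β_S, from CC.S) and 35/40 (a2, from CC.S) — close to the
nominal 36.4/40.  Two properties of the design are worth knowing.
First, fecundity from herd counts alone is only weakly identified: the
counts begin ~one month after the pulse, so `f` separates from
early-calf mortality only by extrapolation, and the HC-only posterior
can be overconfident at fixed truth; the calf-detection data, which
start within two weeks of the pulse, resolve this.  Second,
single-study estimates of the season effect are wide (posterior sd
≈ 0.2–0.3 on the log scale): point estimates of the wet-season hazard
ratio scatter substantially between replicates even though interval
coverage is nominal — consistent with that effect reaching only
"substantial" evidence in a full-scale study.

## Problem sizes

The default test and acceptance runs use reduced-but-faithful scales
chosen as ordinary practice for simulation studies: study-design
replicates at 2 chains × 3000 steps; the acceptance script at 4 chains ×
4000 steps with 1000 posterior projection runs; full production runs
would use the 6 chains × ≥10,000 steps the `metropolis_sample` defaults
encode and 5000 projection runs.

## Known limitations

* Entry-age (tooth-aging) uncertainty is ignored; a measurement-error
  model is future work.
* The herd-count model assumes binomial classification with no
  overdispersion and no sexing/aging error.
* Sequential moment-matching drops posterior correlations; the joint
  oracle bounds the resulting shift at ~0.2–0.35 SD on shared hazard
  parameters for study-scale data.
* The location covariate is a single signed distance; no two-dimensional
  space, no predator fields, no density dependence.
* Year-specific calf hazards in HC.Y share the adult year-effect
  machinery; identifiability at reduced scale is weaker than for the
  pooled rates.
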