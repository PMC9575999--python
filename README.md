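# wildemo

Bayesian vital-rate estimation and population projection for a migratory
ungulate population (blue wildebeest cows and calves), built for
demographic studies that combine three observation streams collected
around radio-collared adult females:

1. **Collared-cow survival** (CC) — dated re-sightings with
   interval-censored deaths, left-truncated at a tooth-estimated entry age;
2. **Herd-composition counts** (HC) — classified calves and cows in herds
   located through the collared animals;
3. **Calf detections** (CD) — per cow-year binary sequences of whether a
   calf was seen with its mother, with imperfect detection.

The package estimates age-specific survival, fecundity, first-year calf
survival, recruitment, calf dissociation, and season/location/year effects
on mortality risk, then checks the self-consistency of the estimated vital
rates with a biannual Leslie-matrix projection.  A synthetic-data generator
with the study's observation structure makes every stage testable against
known truth.

## The model

Mortality hazard follows Siler's five-parameter competing-hazard form —
a declining immature component, a constant, and an exponentially rising
senescent component —

```
h(a) = a1·exp(−b1·a) + a2 + a3·exp(b3·a),
```

modified multiplicatively by covariates (proportional hazards on the log
scale):

```
h(a, x) = h(a) · exp(β_S·[wet season] + β_L·distance + β_Y[year]),
```

where distance is km along the one-dimensional migratory axis from a
southeastern reference point, and the year effects **β**_Y sum to zero.
Survivorship is the closed form `S(a) = exp(−H(a))` with `H` the cumulative
hazard; covariate paths are integrated piecewise at calendar-month
resolution.  Calves separate from their mothers ("dissociation") with
hazard `γ_D·(a − 0.75)` beyond age 0.75 yr.  The calf-detection likelihood
is a hidden-state forward recursion over {no calf born, calf present, calf
dead, calf dissociated}, with detection probability *p* while the calf is
present and *q* otherwise.

Inference is random-walk Metropolis sampling on transformed scales, run as
a sequence of model stages (CC → CC.S → CC.L → CC.Y → HC → HC.Y → CD →
CD.Y) in which the posterior of the shared hazard parameters from each fit
becomes the prior for the next, while each observation model estimates its
own vital rates.  Posteriors are summarized by expected values, shortest
90.9% highest-posterior-density intervals (the level whose evidence ratio
Pr/(1−Pr) equals 10), one-sided lower credible limits, and log10 evidence
ratios.  Interannual variation is summarized by `maxR = exp(range(ln h))`
and `meanR = exp(mean |ln hᵢ − ln hⱼ|)` over year pairs.

The Leslie projection uses 51 six-month age classes (ages 1–26, oldest
absorbing), a dry-season step containing the 1 October birth pulse and a
wet-season step, fecundity `0.5·f` for cows ≥ 2 yr, recruits entering the
1-yr class a year after the pulse with first-year survival S1, a 50-yr
normalized warm-up to the stable age distribution, and a 5-yr free
projection giving the annual growth rate λ.

## Worked example

```python
from wildemo.simulate import SimulationScenario, simulate_observation_set
from wildemo.stages import standard_stages, sequential_fit
from wildemo.derived import s1_samples
from wildemo.bayes import ev, hpd_interval

scenario = SimulationScenario(seed=5)           # the default study design
data, truth = simulate_observation_set(scenario)
stages = standard_stages(data, include=("CC", "CC.S", "HC", "CD"))
results = sequential_fit(stages, seed=1, n_chains=2, n_steps=1500)

cd = results["CD"].to_frame()
f, s1 = cd["f"].to_numpy(), s1_samples(cd)
```

prints, with the summary code in `scripts/acceptance.py` style:

```
110 cows, 392 herd counts, 190 calf-detection cow-years
fecundity                0.68 (0.62-0.75)
first-year survivorship  0.58 (0.50-0.66)
recruitment to age 1     0.39 (0.33-0.46)
detection p              0.89 (0.87-0.90)
false detection q        0.02 (0.02-0.03)
wet-season hazard ratio  1.69 (LER 2.36, decisive)
annual growth rate       0.919 (0.875-0.960)
```

The generating values were fecundity 0.68, first-year survivorship 0.56,
detection 0.89, false detection 0.02, and a wet-season hazard ratio of
1.27: the fit recovers the reproduction and detection parameters inside
tight intervals, while single-study estimates of the season effect are
honestly wide (the true ratio sits inside the interval; its point estimate
scatters between simulated studies).

Recruitment factorizes exactly as fecundity × first-year survivorship
(0.68 × 0.58 → 0.39 above), the identity the herd-count and calf-detection
models share.

The baseline hazard functionals are available directly:

```python
from wildemo import siler_hazard, longevity, life_expectancy
from wildemo.simulate import DEFAULT_SILER
```

```
annual survival at age 2:  0.909
survivorship to age 1:     0.597
longevity (0.1%):          13.96 yr
life expectancy at birth:  3.89 yr
```

## Command line

```bash
wildemo simulate --seed 3 --outdir data/            # three CSVs + truth
wildemo validate data/                              # exclusion bookkeeping
wildemo fit data/ --outdir run/ --stages CC,CC.S,HC,CD --seed 1
wildemo project run/ --n-runs 5000                  # Leslie projection
wildemo report run/                                 # summary from chains
```

All data formats are plain CSV with ISO-8601 dates; every chain is
persisted as one row per chain×step with a JSON run manifest, and every
reported number is recomputable from the persisted chains.

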