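# timediet

Equivalence modelling of 24-hour time use and diet for adolescent
physical functioning.

## The problem

How adolescents spend their day — sleep, self-care, screen time, quiet
time, physical activity, school-related activities, domestic/social
activities — and what they eat are both linked to health. Because the
seven daily durations always sum to 24 h, and because different
behaviour changes can produce the same predicted benefit, a natural
question is: *which combinations of feasible time-use and diet changes
are predicted to be equivalent for physical functioning?* `timediet`
implements that analysis as a reusable, tested pipeline for
epidemiologists and health-behaviour researchers, together with a
synthetic-cohort generator so every stage can be validated with known
ground truth (individual-level cohort data of this kind is typically
access-restricted).

## The model

The day is treated as a 7-part composition **x** closed to 1440 min.
Diary zeros are replaced by small values (≤ 10 min) with an EM-style
log-ratio imputation, and the composition enters the model as six
isometric log-ratio (ilr) coordinates **z** = **V** ln **x**, where
**V** is an orthonormal sequential-binary-partition basis. With diet
serving scores *d* (fruit and vegetables 0–9, discretionary foods 0–12,
sugar-sweetened beverages 0–6) and covariates (age, sex, socioeconomic
position), the outcome model is ordinary least squares on a Box-Cox
transformed physical-functioning score *y* (PedsQL, 0–100):

    bc(y + s; λ) = β₀ + β_z′ z + β_d′ d + β_c′ c + ε,   ε ~ N(0, σ²)

λ is estimated by profile likelihood on [−5, 5]; the composition's
overall association is the partial F test of the six ilr coordinates as
a block (invariant to the basis chosen); diet associations are reported
as standardized betas.

The *equivalence engine* then starts from a reference day (compositional
mean rounded to the 10-min grid; mean serves rounded to integers) and
enumerates every zero-sum time reallocation within ±30 min per behaviour
in 10-min steps (60,691 vectors) crossed with every feasible diet change
within ±1.5 serves in 0.5-serve steps (294 triples at the default
reference — 17,843,154 combinations). Each combination's predicted
outcome difference is computed on the back-transformed 0–100 scale with
covariates fixed at their mean/mode, and combinations are binned into
equivalence bands around ±0.5, 1, 1.5, 2, 2.5 points. All options in a
band are "equivalent" behaviour changes; bands can be summarised per
behaviour or explored interactively, one behaviour choice at a time.

## Worked example

```python
from timediet import (GeneratorConfig, TIME_USE_PARTS, generate_cohort,
                      score_cohort, replace_zeros, fit_model,
                      composition_block_test, standardized_betas,
                      reference_profile, enumerate_options, summarize_options)
from timediet.io import complete_case_filter

cohort, truth = generate_cohort(GeneratorConfig(n=2000), seed=42)
analytic, attrition = complete_case_filter(score_cohort(cohort))
print(attrition)
durations = replace_zeros(analytic[list(TIME_USE_PARTS)].to_numpy(), cap=10.0)
analytic[list(TIME_USE_PARTS)] = durations

model = fit_model(analytic)
block = composition_block_test(model)
print(f"lambda = {model.lam:.2f}")
print(f"block: F({block.df1}, {block.df2}) = {block.F:.1f}, p = {block.p:.3g}")
print(standardized_betas(model).round(3).to_string(index=False))

ref = reference_profile(durations, analytic[["fruit_veg", "discretionary", "ssb"]].to_numpy())
table = enumerate_options(model, ref)
print(f"{table.n_rows:,} combinations; +2.5 band: {table.band_counts()[2.5]:,}")
top = summarize_options(table, 2.5)
print(top[top.behaviour == "physical_activity"].round(1).to_string(index=False))
```

prints

```
{'provided': 2000, 'valid_time_use': 2000, 'complete_diet': 1898,
 'complete_physical_functioning': 1893, 'complete_covariates': 1893}
lambda = 1.93
block: F(6, 1880) = 266.1, p = 9.96e-247
     variable  std_beta   p
    fruit_veg     0.151 0.0
discretionary    -0.116 0.0
          ssb    -0.101 0.0
17,843,154 combinations; +2.5 band: 103,787
 band         behaviour  delta  count  percent
  2.5 physical_activity    0.0    184      0.2
  2.5 physical_activity   10.0   4697      4.5
  2.5 physical_activity   20.0  26272     25.3
  2.5 physical_activity   30.0  72634     70.0
```

Reading the output: the complete-case chain kept 1,893 of 2,000
simulated adolescents; the estimated Box-Cox exponent is close to the
generator's true value (2); the time-use composition is strongly
associated with physical functioning (the block F test), fruit/vegetable
intake is positively and discretionary food and sugary-drink intake
negatively associated (standardized betas); and of the ~104k behaviour
changes predicted to improve physical functioning by ≈ 2.5 points, 70%
require the full +30 min/day of physical activity — the behaviour with
the strongest per-minute leverage — and none allow reducing it.

The same pipeline is available from the shell:

```bash
timediet run --output-dir out --seed 42      # simulate -> fit -> enumerate -> summarise
timediet simulate --n 2000 --seed 1 --out cohort.csv
timediet fit cohort.csv --out model.json
timediet explore out/options.csv --band 2.5 \
    --selections '[["physical_activity", 30], ["ssb", -1.0]]'
```

`timediet run` writes the simulated cohort, the model artifact
(`model.json`), the banded option table (`options.csv`), per-band
stacked-bar summaries and a `run_log.json` recording every setting,
the seed and the sample size after each filtering step.

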