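# pwidtrends

Analysis toolkit for repeated cross-sectional surveys of people who inject
drugs (PWID), of the kind run by needle-and-syringe-programme surveillance
systems: annual or biennial samples of people currently injecting, each
reporting their age, age at first injection, and year of first injection.

From such data the package estimates:

1. **Trends in population structure** — median and quartiles of age, age at
   first injection, and duration of injecting by calendar year, via quantile
   regression on linear and quadratic terms of the (centred) survey year.
   Age at first injection is analysed by year of initiation, restricted to
   people who started injecting in the past 3 years, to avoid the
   survivorship bias that makes long-ago initiates look younger.
2. **Incidence of injecting** — the annual number of people injecting for the
   first time, N(c), back-calculated from the distribution of reported
   initiation years. A survey in year *t* observes cohort *c* in proportion to
   N(c)·S(t−c), where S(d) = exp(−d/μ) is the probability of still injecting
   *d* years after starting (constant cessation hazard, mean duration μ = 15
   years by default). Dividing observed counts by S(t−c) recovers the
   initiation curve up to scale; evidence from all survey years is combined
   by a Monte-Carlo scheme (multinomial resampling of each histogram,
   inversion per replicate, survey-size-weighted averaging) that yields 95%
   prediction intervals; an external prevalence estimate converts the
   relative curve into absolute annual counts. A sensitivity analysis repeats
   everything over a range of assumed mean durations (10–20 years).
3. **Reproducible cleaning** — an exclusion cascade (non-recent injectors,
   image-and-performance-only injectors, insufficient data, implausible
   records) with derivation of missing fields from the identities
   duration = age − age at first injection and
   year of first injection = survey year − duration, plus an exclusion log
   whose counts always reconcile.

A synthetic-population simulator generates surveys with known ground truth —
a configurable initiation-rate curve, exponential injecting durations,
drifting age at initiation, and realistic data corruption — so every stage of
the pipeline can be validated end to end without access to restricted survey
microdata.

## Worked example

```python
import pwidtrends as pt

scenario = pt.make_scenario(
    "gaussian_peak", years=(1960, 2019), amplitude=10_000,
    peak_year=1998, width=5, age_mean_start=20, age_mean_end=30)
population = pt.simulate_population(scenario, mu=15, seed=1)
design = pt.SurveyDesign(
    survey_years=list(range(1990, 2020)),
    sample_size={t: 2000 for t in range(1990, 2020)}, seed=2)
clean, log = pt.clean_survey_table(pt.simulate_surveys(population, design))

fit = pt.IncidenceModel.from_survey_table(clean, mu=15).fit(n_mc=500, seed=3)
print(fit.summary())
anchored = fit.calibrate(pt.CalibrationAnchor(ref_year=2011, prevalence=87_000))
print(anchored.summary())
ages = pt.QuantileTrendModel(clean, "age").fit()
print(f"median age 1990: {ages.fitted_at(0.5, 1990):.1f}; 2019: {ages.fitted_at(0.5, 2019):.1f}")
```

prints

```
Back-calculated initiation curve
  scale: relative; mean duration mu = 15 y; cohorts 1978-2018
  surveys combined: 30 (60000 records)
  peak cohort year: 1997 (N_hat = 0.07144)
  95% prediction intervals from 500 multinomial replicates
Back-calculated initiation curve
  scale: absolute; mean duration mu = 15 y; cohorts 1978-2018
  surveys combined: 30 (60000 records)
  peak cohort year: 1997 (N_hat = 1.524e+04)
  95% prediction intervals from 500 multinomial replicates
median age 1990: 26.6; 2019: 46.6
```

The simulated epidemic peaked in 1998; the back-calculation places the peak
at 1997 from survey data alone, and — after anchoring to an assumed 87,000
people currently injecting in 2011 — estimates about 15,000 initiations per
year at the peak. The fitted median age of the surveyed population rises from
27 to 47 as the large 1990s cohorts age, the cohort effect the trend analysis
is designed to expose.

There is also a CLI mirroring the library
(`pwidtrends all scenario.yaml --out results/`), with subcommands
`simulate`, `clean`, `trends`, `incidence`, `sensitivity` and `all`; it writes
a clean table, exclusion log, trend and incidence CSVs, and a manifest that
suffices to rerun the bundle byte-for-byte.

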