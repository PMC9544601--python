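# Methods

## The demographic model

The package treats the injecting population as a set of annual initiation
cohorts. N(c) people inject for the first time in calendar year c; each
person's injecting career lasts an exponentially distributed time with mean
μ years (a constant hazard of cessation, which pools stopping and death into
a single exit process). Time is discrete at whole calendar years: a person
initiating in year c with career length D is "currently injecting" in survey
year t iff c ≤ t and t − c < D. Under this convention the probability of
still injecting d whole years after initiation is

    S(d) = exp(−d/μ),  d = 0, 1, 2, …

and the simulator and the estimator share exactly this survival function, so
the back-calculation is the precise inverse of the generative model rather
than an approximation to it.

A cross-sectional survey in year t samples people currently injecting, so the
expected share reporting initiation year c is proportional to N(c)·S(t−c).
The back-calculation divides the observed initiation-year counts n_t(c) by
S(t−c) and renormalises, giving each survey's estimate of the relative
initiation curve over the cohorts it can see (c ≤ t).

## Combining surveys and prediction intervals

Surveys are combined as a weighted mean of the per-survey relative estimates,
with weights proportional to survey size (proportions from larger surveys are
more precise, and size weights stay stable where counts are zero). Monte-Carlo
prediction intervals resample each histogram's counts from a multinomial with
the observed proportions, re-invert and re-combine per replicate, and take the
2.5th/97.5th percentile band; the band is forced to bracket the point estimate.
This scheme is a deliberate reconstruction of "combine evidence across survey
years" from first principles — the simplest procedure that yields wider
intervals for cohorts informed by fewer surveys — and interval widths should
not be expected to match any specific published analysis exactly.

Two numerical guards matter. Cohort support is truncated at d_max = ⌈5μ⌉
years before a survey: beyond that, S(d) < e⁻⁵ and dividing by it turns
single sampled records into enormous cohort estimates. Zero-count cohorts
contribute an estimate of zero from that survey — no pseudo-count by default,
so the estimator is transparent; add-half smoothing is available via
`pseudo_count=0.5` but off by default.

A known property of this combination (visible in tests, documented here
deliberately): each survey normalises over only the cohorts it can see, so
early surveys — which cannot see later cohorts — contribute slightly inflated
relative values for early cohorts. On the England-like test scenario this
shifts the estimated peak about one year early and is the main reason the
truth correlation is ~0.95 rather than 1. Correcting it would require joint
(e.g. EM-style) estimation across surveys, which is out of scope; the
per-survey inversion remains exactly unbiased when all surveys post-date the
whole epidemic.

## Calibration

An external prevalence estimate P (people currently injecting in reference
year t*) fixes the scale: the relative curve is multiplied by
k = P / Σ_{c≤t*} N(c)·S(t*−c), making the implied prevalence at t* equal P
exactly. Prediction bounds are scaled by the same k; if the anchor carries an
uncertainty interval, each Monte-Carlo replicate's k is additionally scaled
by a uniform draw between the interval's relative bounds (uniform because
anchors typically come with hard plausibility bounds rather than a standard
error). Anchor uncertainty never moves the point estimate.

The sensitivity analysis refits the whole pipeline at μ ∈ {10, 12.5, 15,
17.5, 20} years by default. Shorter assumed durations mean fewer early-cohort
survivors per observed record, inflating early cohorts relative to recent
ones; the early/late cohort ratio is therefore strictly decreasing in μ.
Every fit seeds its random generator from the pair (seed, μ), so adding a μ
to a sensitivity run leaves the other curves bit-identical.

## Quantile trends

Conditional quantiles (quartiles by default) of age, age at first injection
and injecting duration are modelled as β₀ + β₁y + β₂y², with y the calendar
year centred at the midpoint of the observed range (pure conditioning; fitted
values are unchanged). Fitting minimises the check loss via statsmodels'
quantile regression, with one shortcut: when the outcome is exactly quadratic
in year (constant, linear or quadratic noise-free signals), the least-squares
interpolant has zero residuals and minimises the check loss for every τ, so
it is returned directly — this makes degenerate and noise-free cases exact
instead of depending on iterative-solver termination. Reported "median in
year Y" is the model's fitted value at Y, not the raw per-year sample median.
Fitted quantiles are sorted within each year so the reported quartiles never
cross. Confidence intervals, when requested, are percentile bootstrap over
records (200 resamples by default); they are secondary to the point trends at
surveillance sample sizes.

Age at first injection is estimated by **year of initiation**, restricted to
records with 0 ≤ survey_year − year_first_inj < 3 ("past 3 years" = gaps
{0, 1, 2}). The restriction removes survivorship bias: if people who start
younger inject for longer, cohorts observed long after initiation
over-represent young starters. The simulator exposes this mechanism through
`duration_age_gradient`, which makes an individual's mean duration
μ·exp(−γ·(age − cohort mean age)); with γ > 0 the windowed estimator is
demonstrably closer to the cohort truth than the all-records estimator.

## Cleaning

Missing fields are derived from duration = age − age_first_inj and
year_first_inj = survey_year − duration, iterated to a fixed point, never
overwriting observed values. The exclusion cascade then removes, in order:
(i) people not injecting recently (with three recency modes: `strict` drops
unknowns; `assume_recent_pre1993` keeps unknowns for survey years ≤ 1992,
when recency questions were not asked and ~90% of participants injected
recently; `last_inj_year` keeps records whose reported year of last injection
is the survey year or the year before, the mid-1990s questionnaire dialect);
(ii) image-and-performance-only injectors (psychoactive = no; unknown is
retained since not all surveys ask); (iii) records still missing a core
field; (iv) implausible records. Each record is counted once, at the first
rule it violates, so input = retained + Σ exclusions always.

Implausibility means: age at first injection above current age, initiation
year after the survey year, negative duration, a reported duration that
contradicts age − age_first_inj, or duration and survey_year −
year_first_inj disagreeing by more than ±1 year. The one-year grace on the
year arithmetic reflects whole-year reporting granularity (someone surveyed
in March who started in November "last year" has duration 0 but a year gap
of 1); the choice of ±1 is this package's own and inconsistent-but-complete
records beyond it are excluded rather than arbitrated. Sex and region are
pass-through strata, never exclusion criteria.

## The synthetic-data generator

`make_scenario` provides two presets: `constant`, and `gaussian_peak`
(rate(c) = A·exp(−(c−peak)²/2w²)), the single-wave shape matching the UK
narrative of a rise through the 1980s, a late-1990s peak and a post-2000
decline. The England-like test conditions use amplitude 10,000/year at a 1998
peak with width 5 years, μ = 15 years, and 30 annual surveys of 2000 records
(1990–2019) — round numbers of the order of the real surveillance series.
Age at initiation is truncated normal (lower bound 15 years, sd 5) with a
mean drifting linearly from 20 to 30 years over the scenario, the simplest
shape that reproduces a rising median age at initiation. Survey sampling is
uniform among current injectors.

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: engagement bias (new injectors under-represented at
services; available only as the optional duration–age gradient, not as a
sampling weight), repeat participation across rounds, regional structure
beyond a pass-through label, recall error in reported initiation years, and
any departure from exponential career lengths. Parameter-recovery results
here demonstrate the estimator is consistent with its own assumptions at
realistic sample sizes, not that those assumptions hold in the field.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| μ (mean duration) | 15 | years | midpoint of published modelling assumptions (8–20 y); sensitivity run covers 10–20 |
| sensitivity μ grid | 10, 12.5, 15, 17.5, 20 | years | brackets the plausible cessation range |
| initiation window | 3 | years | "past 3 years": gaps {0, 1, 2} |
| τ levels | 0.25, 0.5, 0.75 | — | median and IQR, the standard surveillance summary |
| n_mc | 1000 | replicates | percentile stability at 2 decimal places; 500 used in the scaled test runs |
| d_max | ⌈5μ⌉ | years | S(d) < e⁻⁵ beyond; variance control |
| consistency tolerance | ±1 | years | whole-year reporting granularity |
| bootstrap resamples | 200 | — | CI precision secondary to point trends |

## Problem sizes used in the test runs

The England-like validation scenario simulates ~125,000 injecting careers and
60,000 survey records (30 × 2000); with 500 Monte-Carlo replicates the full
pipeline runs in a few seconds. The prediction-interval coverage check uses
200 replications of a 15-survey × 500-record design with 200 replicates each.
These sizes were chosen to keep the whole validation suite fast while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- μ is an assumption, not estimated from data; only its level is
  sensitivity-tested, not the exponential shape.
- The survey-combination scheme has the small early-cohort inflation
  described above.
- Prediction intervals capture multinomial resampling noise (plus optional
  anchor uncertainty) only — not model misspecification, not selection bias.
- Calibration assumes the anchor measures the same population the surveys
  sample.
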