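# Methods

## Scope and shape

The package is an analysis pipeline over synthetic multi-survey smoking
micro-data: every computational step lives in `src/smoketrends/` and is
imported by the numbered drivers in `analysis/`, the test suite and
`scripts/acceptance.py`. The synthetic generator is first-class code, not
a fixture: it defines the study conditions under which all downstream
claims are validated.

## The prevalence surface and what the generator emulates

Smoking probability is modelled on the log-odds scale as

    logit p = β₀(sex) + age(a) + edu(e, t) + period(a, t)

- **Age effect**: piecewise-linear with knots at 18, 25, 60, 80 years,
  peaking at 25. Defaults (men): −0.6 at 18, 0 at 25, −0.25 at 60, −1.4
  at 80; women fall much faster after 60 (−3.5 at 80), so female smoking
  at 70+ stays below 5% before 2010.
- **Education**: offsets for low and secondary vs high education. Men:
  log 3.5 and log 2.0, constant over time. Women: log 2.0 and log 1.5 at
  the 2006 reference, with the low-vs-high offset drifting by +0.0693 per
  year — the gradient widens from about 1 to about 4 across 1996–2016.
  The widening is deliberate: it is what makes the female pooled effect
  strongly heterogeneous (I² ≈ 74% in the default scenario) while the
  male gradient pools homogeneously (I² ≈ 7%).
- **Period**: men flat until 2007, then −0.045 log-odds per year, which
  produces a decline of roughly 10 percentage points in standardized
  prevalence over 2008–2016 from a pre-decline level near 56%. Younger
  women (< 55) rise at +0.02/yr to a 2005 peak then fall at −0.03/yr;
  women 55+ follow a slow +0.01/yr rise from near zero.
- **Record-level nuisance parameters**: among current smokers 4.5% smoke
  occasionally (inside the 2–7% band that motivates the harmonization
  module); 0.8% of daily and 45% of occasional smokers report fewer than
  100 lifetime cigarettes, and 10% of never-smokers report ≥ 100, so the
  whole-sample understatement from the 100-cigarette filter comes out
  near 0.8–0.9 percentage points.
- **Quitting**: for men aged 30+ surveyed after 2007, the accumulated
  year-on-year decline of the surface at the respondent's age is
  converted into former-smoker status with a dated quit year; below 30
  the decline is read as reduced initiation and produces never-smokers.
  The split between quitting and initiation is a modelling choice — the
  observable (prevalence) cannot identify it — so it is a documented
  convention, not an inference.

The default scenario comprises the 17 RLMS-like annual rounds (1996,
1998, 2000–2010, 2013–2016; the 2011–2012 rounds are excluded, mirroring
the panel-replenishment exclusion in the source series) with sample sizes
7,302 (≤ 2009) and 11,634 (≥ 2010), plus five cross-sections covering the
three question variants, narrow age ranges (50–79, 25–60) and sizes from
1,109 to 11,406. One integer seed drives everything; per-survey streams
are spawned deterministically from it (`numpy` `SeedSequence.spawn`).

What the generator does **not** emulate: panel structure and attrition
between rounds, survey design weights, geographic clustering, item
nonresponse, and any correlation between education and age beyond what
the marginal distributions induce. Tests passing under these conditions
therefore validate the estimators' arithmetic and statistical behaviour,
not robustness to the sampling pathologies of real surveys.

## Harmonization

The conventional question's ambiguity is a per-record Bernoulli capture
of occasional smokers with probability 0.5 by default; at any capture
probability the implied prevalence ordering daily ≤ conventional ≤
WHO-current holds by construction, and the 2–7% occasional share bounds
the distance between the definitions. The 100-cigarette filter measure
refuses records with missing lifetime flags rather than imputing.

## Standardization

Age strata are the 5-year groups of the 1976 European standard
population, truncated to the survey's range (18–19 carries 2/5 of the
15–19 weight). The education standard defaults to low 0.30 / secondary
0.50 / high 0.20 (a mid-1990s Russian adult structure; configurable,
since the source standard's exact proportions are not published). The
joint standard is the product of the marginals — the two standards come
from unrelated sources, so independence is the only defensible joint
table. Empty strata renormalize the remaining weights and reduce the
estimate's `coverage`; the pipeline excludes a survey-year from the
standardized table when coverage falls below 0.9, which is what removes
the old-age-only and working-age-only cross-sections.

## Meta-analysis

Stage 1 aggregates a study's records to education × 10-year-age-band
binomial cells and fits the logistic model by IRLS (statsmodels GLM);
this is exactly the record-level MLE but an order of magnitude faster.
High education is the reference, so pooled ORs read "low vs high";
secondary-vs-high is estimated alongside and pooled separately. Studies
with an absent education extreme, a single outcome within an extreme, or
a diverging estimate (|log OR| > 15) are excluded with a logged reason.
DL pooling implements the moment estimator exactly as defined; with one
study, τ² = 0 and I² is reported missing (Q has zero degrees of
freedom). Meta-regression estimates τ² by REML Fisher scoring (tolerance
1e−8 on τ², max 200 iterations, non-convergence is an error carrying the
iteration trace); the method-of-moments estimator is available as a
cross-check, and both are verified against R's `metafor` on a frozen
fixture. The trend stage regresses age-standardized prevalence (not its
logit) on year, so slopes read directly in percentage points per year.

## Attribution

The mortality model is multiplicative: cell deaths = never-smoker
baseline × M, with M = 1 + (HR_a − 1)(p_cur + Σ_τ p_f(τ) r(τ)). The lag
profile r(τ) interpolates (0, 1), (5, 0.3), (10, 0): 70% of the excess
CVD risk is gone five years after quitting and all of it within ten.
Age-band hazard ratios default to 2.0 / 1.7 / 1.3 for 15–49 / 50–64 /
65+. These defaults are explicit placeholders — the analysis this
reconstructs estimated its hazard ratios from external cohort data that
are not published with it — so the absolute avoided-death totals scale
with whatever HRs, baseline rates and populations are configured; the
self-consistency property (recovering the generator's built-in difference
to < 0.1% without noise) is what the tests pin down. The counterfactual
freezes the 2007 prevalence with no quitting. The "share of the observed
reduction" framing compares avoided deaths with the drop in deaths
relative to the 2007 mortality regime (2007 rates applied to each year's
population); in the synthetic world the smoking decline is the only
mortality change, so this share is 100% by construction (up to Poisson
noise), unlike in reality where other drivers dominate.

## Survivor selection

The cohort model is deliberately quitting-free to isolate the selection
mechanism. The default never-smoker hazard is Gompertz
h(x) = 8·10⁻⁴·e^{0.075x} per year (h(40) ≈ 0.016, a high-mortality
male-like schedule); with p₀ = 0.6 at entry age 25 and HR = 2 the
uniform-age-average reduction over 25–75 is ≈ 26% — the "about one
quarter" vicinity — while the endpoint contrast at 75 is far larger
(≈ 87%). Whether "between 25 and 75" means an average or an endpoint
contrast is genuinely open; both are exposed, the average is the default
summary. Survival integrals use the Gompertz closed form when available
and adaptive quadrature otherwise.

## Numerical and design choices

- Binomial SEs are used throughout standardization; a stratum with 0 or
  n smokers has SE 0 rather than a continuity correction.
- REML τ² is clamped at 0 each iteration; convergence is relative on
  1 + τ².
- The pipeline writes nothing on failure: outputs accumulate in memory
  and are flushed only after every requested stage succeeds, each CSV
  stamped with a 16-hex-digit SHA-256 hash of the analysis configuration
  (output directory excluded).
- Problem sizes: the default scenario is ~174k records across 22
  surveys; the parameter-recovery check uses 200 full-scenario replicates
  for pooled-CI coverage and 500 effect-level replicates for
  meta-regression slope coverage, which keeps the whole suite under two
  minutes of compute.

## Known limitations

Former-smoker accumulation uses the respondent's current age for the
whole quit history (a cross-sectional approximation, not cohort
bookkeeping); attribution age bands are coarse (3 bands) and population
aging within the window is not modelled; the conventional-question
capture probability is a single global parameter though real surveys
plausibly differ; no survey weights or finite-population corrections are
applied anywhere.
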