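# Methods

`morphotrend` asks a monitoring question: when aerial surveys of a
migratory caribou herd are years apart, can morphological traits
measured on captured or harvested animals — hind foot length (HFL, cm),
live body mass (kg), a body-fat index — stand in for an abundance
estimate? The package implements the full statistical chain needed to
answer it on a given data set, and a synthetic-data generator that lets
every stage be exercised and calibrated without field data.

## 1. Population trajectory as a latent-size prior

Surveys arrive as point estimates with heterogeneous 95% (sometimes 90%)
confidence intervals, or none at all. The reconstruction
(`morphotrend.trajectory`):

1. **Relative observation error** of a survey is the interval
   half-width divided by the estimate. The half-width convention is
   pinned by internal consistency of published numbers: a
   218,000 ± 15,894 survey has ratio 0.073, in line with its herd's
   mean error of 0.10, while the full-width reading (0.146) is not.
2. Surveys without an interval receive the herd's **mean relative
   error**: bounds `estimate · (1 ± mean_error)`.
3. Years with both a field and an integrated-population-model (IPM)
   estimate keep the **widest envelope** (lowest LCI, highest UCI).
4. Three independent **loess** curves (tricube kernel, local degree 2,
   no robustness iterations; span is a per-herd setting, 0.4–0.75) are
   fitted through the estimates, the lower bounds and the upper bounds,
   and evaluated at every integer year between the first and last
   survey. Years outside that range are never extrapolated; trait
   records linking to them are dropped and counted.
5. The per-year **sd** of the latent-size prior is
   `(UCI − LCI) / (2 · 1.96)`. Bounds of mixed 90/95% level are used as
   given and the 1.96 divisor applied uniformly; the divisor is exposed
   as the `z` argument for sensitivity runs. The three curves are not
   constrained to nest; an inverted pair after smoothing is swapped
   with a logged warning.
6. **Phase labels** (growth/decline) come from the sign of the smoothed
   trajectory's year-over-year difference, majority-filtered over a
   3-year window so survey noise near a peak cannot create one-year
   phases. No published procedure exists for this step; the filter
   width is a package choice and the change-point year is logged.

## 2. Trait harmonization

`morphotrend.harmonize` turns raw capture records into analysis-ready
observations:

* **Conversions** (fixed parts of the retained mixed-model
  calibrations, year random effect at its zero mean):
  `HFL = −3.17 + 1.50 · metatarsus` and
  `live mass = 13.33 + Age + 1.27 · eviscerated mass`. The age offsets
  of the mass equation are not published; they default to 0 per class
  and can be overridden from a fitted `ConversionModel`. Converted and
  directly measured values are pooled, with provenance kept in a
  `source_measure` column for sensitivity analyses.
* **Calibration fitting** (`morphotrend.conversion`) refits these
  conversions on paired data: candidates {null, +sex, +age, +sex+age,
  +sex×age}, each a linear mixed model with a year random intercept,
  fitted by ML (statsmodels `MixedLM`), ranked by AICc, with the Arnold
  rule — among candidates within ΔAICc < 2 of the best, keep the one
  with the fewest fixed parameters. A Shapiro residual-normality
  p-value is attached as a diagnostic.
* **Age classes**: newborn ≤ 1 month, yearling 13–24 months, adult
  ≥ 25 months; for HFL the adult threshold is 2.5 years (ages 25–29
  months are excluded from skeletal analyses, not mislabelled), because
  leg bones grow until about that age.
* **Seasons**: late winter Jan–Apr, summer May–Aug, early winter
  Sep–Dec; newborn analyses keep June records only.
* **Date standardization**: per stratum (herd, or herd × season for
  seasonal analyses), the trait is regressed on Julian day with
  polynomials of order 1–5; order k+1 is kept over order k only when a
  nested ANOVA F-test improves the fit at α = 0.05. Values are adjusted
  to the stratum's mean measurement day,
  `value − (poly(day) − poly(mean_day))`. Days are standardized
  internally before fitting (raw day⁵ spans ten orders of magnitude and
  destroys the conditioning of the F-tests). Conversions are applied
  before standardization.
* **Inclusion filters**, in a fixed documented order, each step
  counted in a `FilterReport`: duplicates and implausible values
  (HFL 20–70 cm; mass 2–15 / 20–80 / 40–160 kg by class; fat 0–30 —
  configurable windows, since "aberrant" is not defined anywhere),
  herd switchers, male yearlings/adults (strong sexual dimorphism,
  < 6% of records), years with fewer than 5 individuals (computed per
  trait), trait × herd combinations with fewer than 5 years, and — for
  seasonal analyses — season × herd cells with fewer than 30
  individuals. Filtering is idempotent.
* **Linkage**: HFL of yearlings/adults reflects conditions during
  skeletal growth and links to population size at cohort year + 1;
  newborn HFL to the cohort year; mass and fat to the year of
  measurement.

## 3. The errors-in-variables regression

For one herd × trait × age-class stratum (`morphotrend.eiv`):

    trait_i      ~ Normal(mu_year(i), sigma)
    mu_year      = alpha + beta · x_year                   (annual)
    mu_year      = alpha + beta_phase · x_year             (phase model)
    mu_year      = alpha_season + beta_season · x_year     (seasonal model)
    x_year       ~ Normal(traj_mean_year, traj_sd_year),  x_year ≥ 0

with `x` in units of 10,000 individuals. The scale is fixed by the
published ΔY/ΔX reporting pairs (e.g. a slope of 0.61 described as 3 kg
per 50,000 individuals); one published pair (−0.32 described as −3 cm
per 50,000, which implies −1.6 on this scale) is inconsistent and is
flagged rather than forced. Priors: each `beta` ~ Uniform(−1, 1);
`alpha` ~ Uniform over the trait's plausibility window; `sigma` ~
Uniform(0, cap) with caps HFL 10 cm, mass 30 kg, fat 10 (the sources
describe these priors only as uninformative/weakly informative; the
bounds here are the package's own). One residual sd is shared across
phases and seasons of a model, matching the repeated σ rows of the
published summaries; the residual is a single i.i.d. term per
observation, with repeat-captured individuals flagged so a sensitivity
variant with an individual intercept can be added. The phase model
requires at least 5 years of data in each phase.

**Sampler.** Every full conditional is available in closed form:
truncated Normals for `alpha`, `beta` and each latent `x_year`
(conditionally independent given the coefficients), and a truncated
inverse-gamma for `sigma²`. The sampler is therefore plain Gibbs — no
tuning, exact stationary distribution, fully reproducible from a seed.
`alpha` and `beta` are drawn jointly as one multivariate-Normal block:
with `x` far from zero they are near-collinear, and coordinatewise
updates mix pathologically (Rhat ≈ 6 in early experiments); the blocked
draw restores n_eff in the thousands. Box-prior violations of the
blocked draw are handled by rejection (≤ 50 tries) with a
coordinatewise truncated fallback. `log_posterior` exposes the target
density as the contract any alternative sampler must satisfy, and the
test suite checks the Gibbs output against closed-form least-squares
posteriors in the conjugate sub-case.

**Protocols.** The full protocol is 3 chains × 100,000 iterations,
burn-in 60,000, thinning 10 (12,000 retained draws); the reduced
desk-scale protocol used by the packaged recovery experiments and the
acceptance script is 3 × 10,000, burn-in 5,000, thinning 5 (3,000
draws). Diagnostics: split-chain potential scale reduction factor
(Rhat < 1.1 required for a "converged" flag) and an
autocorrelation-based effective sample size with Geyer initial-positive
truncation. A slope is called significant when its equal-tailed 95%
credible interval excludes zero. `effect_translation` converts a slope
to the trait change implied by a head-count change
(`beta · Δpop / 10,000`).

## 4. The synthetic-data generator

`morphotrend.synthetic` emulates the study conditions:

* **Trajectories** are piecewise log-linear between anchor sizes
  (population change is multiplicative); shapes: growth, decline, peak,
  trough. Survey estimates are Normal(true, rel_error · true / 1.96)
  truncated positive — `rel_error` is the 95% half-width ratio — and
  half of the surveys (configurable) carry no interval, to exercise
  imputation.
* **Individuals** get trait values
  `alpha(+season) + beta(+phase/season) · size/10⁴ + date_poly(day) + Normal(0, sigma)`,
  with sex, age months, cohort year and measurement date laid out so
  the harmonization link rules map each record back to the population
  year whose size generated it. Ten percent of yearlings/adults are
  re-measured the following year to exercise repeat-measurement
  handling.
* **Presets** (`presets.json`) encode one generating scenario per
  published herd × age class × trait relationship, using the published
  α, β, σ as generating values. Scenario choices the sources do not
  fix, chosen once as the realistic emulation: Porcupine surveys are
  annual at rel_error 0.10 (the published loess used ~13 Porcupine
  surveys; spreading 7 sparse points under span 0.4 degenerates to
  3-point interpolation); RAF/RG presets use an annual series at
  rel_error 0.15, because their trait eras are covered by annual IPM
  estimates whose published intervals are ±6–8%, not by the poor early
  surveys that dominate the herds' 0.46/0.33 mean errors; Beverly
  presets keep the published 0.32 error but separate the survey record
  (a 1971–1987/94 trough at ~2-year cadence) from the trait-measurement
  window (`trait_years`, 1980–87 growth years), mirroring the shaded
  measurement periods of the herd histories. Per-year sample sizes
  (10–80 depending on preset) are pragmatic: the sources publish only
  totals and filters.

**What the generator does not emulate** — and therefore what passing
recovery tests do not establish about field data: observer and
protocol differences between teams and decades (the real HFL series
contain between-herd offsets of tens of percent), non-June birth dates,
age-determination error, selective sampling by hunters, spatial
heterogeneity within a herd's range, and any density-independent
environmental driver of condition. Recovery results show the estimator
chain is correct under its own assumptions, not that the assumptions
hold in the field.

## 5. Numerical choices and degenerate inputs

* Loess windows always contain at least degree+1 points; a window of
  coincident x-values returns their mean; a vanishing tricube weight
  set is ridged by 1e-12.
* Truncated-Normal draws use the inverse-CDF method with the Normal CDF
  clipped to [1e-15, 1 − 1e-15]; a zero prior sd clamps a latent size
  at its mean exactly (used for the "ignore size uncertainty"
  sensitivity variant).
* `sigma²` draws use rejection against the Uniform cap (≤ 100 tries,
  then a draw pinned just under the cap); with realistic data the
  rejection never triggers.
* Chains are seeded by spawning a `numpy` `SeedSequence` per chain from
  the user seed; identical seeds give byte-identical outputs end to
  end.
* Empty survey lists, all-missing intervals, phases with < 5 years,
  strata emptied by filters, single chains passed to diagnostics, and
  constant chains (ESS undefined; reported as the total with a warning)
  all raise or warn explicitly.

## 6. Recovery experiments and problem sizes

`recovery_experiment` simulates a preset repeatedly, refits with the
reduced protocol and reports bias, RMSE and 95% credible-interval
coverage of the slope. The packaged experiments use 20–50 replicates
and desk-scale chains; a single preset recovery takes a few seconds on
one CPU. Observed calibration at these scales: coverage close to, but
a few points under, the nominal 95% (the smoothed trajectory's
deviation from the generating trajectory is correlated across years,
which the model's independent annual priors do not fully describe) —
the order of miscalibration a practitioner should expect of the method
itself on real series. Slopes with the narrowest published intervals
(|CI| ≈ 0.03–0.05 on the per-10,000 scale) are recovered with sampling
error comparable to those interval widths, so single-dataset recovery
lands inside them in most but not all replicates.

## 7. Known limitations

* No individual-level random intercept (one σ per model); repeat
  captures are flagged but not modelled.
* No temporal autocorrelation in residuals and no joint multi-herd
  model — models are fitted separately per herd, as in the source
  analyses.
* Phase assignment is deterministic from the smoothed trajectory;
  phase uncertainty does not propagate into the regression.
* The loess span is a setting, not estimated; no objective criterion
  for it exists in the sources.
* No model comparison (DIC/WAIC) across the annual/phase/seasonal
  variants.
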