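# morphotrend

Can body measurements stand in for an abundance survey? Wildlife
managers of migratory caribou (*Rangifer tarandus*) often have long gaps
between aerial surveys but near-continuous streams of morphometric data
— hind foot length (HFL), body mass, body-fat indices — from captures
and harvests. `morphotrend` implements the statistical chain needed to
test whether such traits track herd size: reconstruction of an annual
population trajectory (with uncertainty) from sparse, heterogeneous
surveys; harmonization of three decades of measurement records; and a
Bayesian errors-in-variables mixed regression of each trait on *latent*
population size.

The core model, for individual *i* measured in a stratum of one herd,
trait and age class:

```
Trait_i  ~  Normal(μ_year(i), σ)
μ_year   =  α + β · Pop.size_year                    (annual)
μ_year   =  α + β_phase · Pop.size_year              (growth/decline phases)
μ_year   =  α_season + β_season · Pop.size_year      (seasonal)
Pop.size_year  ~  Normal(μ̂_year, σ̂_year),  truncated ≥ 0
```

Population size enters in units of 10,000 individuals, so β is "trait
units per 10,000 caribou". The per-year prior (μ̂, σ̂) comes from three
loess curves (tricube, degree 2) through the survey estimates and their
lower/upper 95% bounds, with σ̂ = (UCI − LCI)/(2·1.96); surveys lacking
intervals get the herd's mean relative error imputed. Priors:
β ~ U(−1, 1), α uniform over a trait plausibility window,
σ ~ U(0, cap). Sampling is by a blocked Gibbs scheme (all full
conditionals are truncated Normals / inverse-gamma), 3 chains with
split-chain R̂ and effective-sample-size diagnostics; a slope is called
significant when its 95% credible interval excludes zero.

A synthetic-data module generates herd histories (log-linear growth /
decline / peak / trough trajectories, noisy surveys with missing CIs)
and individual records under the same model, including a registry of
presets whose generating (α, β, σ) are the published estimates for each
herd × age class × trait relationship — the basis of the packaged
parameter-recovery experiments.

## Worked example

Simulate the Beverly adult-mass scenario (generating slope
β = 0.61 kg per 10,000, residual σ = 7.90 kg, a 1971–87 survey record
with 32% observation error, traits measured 1980–87), rebuild the
trajectory from the noisy surveys, harmonize and link the records, and
refit with the reduced MCMC protocol:

```python
>>> from morphotrend import run_preset
>>> run = run_preset("beverly_adult_mass", seed=0)
>>> print(run.result.summary.loc[["alpha", "beta", "sigma"]].round(3))
           estimate     lci     uci   rhat     n_eff
parameter
alpha        73.155  69.937  75.439  1.000  1862.897
beta          0.454   0.305   0.685  1.001  1572.581
sigma         7.919   7.519   8.372  0.999  3000.000
```

The slope posterior mean (0.45 kg per 10,000 individuals, one noisy
realization of the generating 0.61 whose published interval is
[0.40, 0.92]) has a 95% credible interval excluding zero — over 50,000
additional caribou this translates (`effect_translation`) to about
+2.3 kg of adult female mass. σ recovers the generating 7.90 kg. `run.trajectory` holds the smoothed
annual size prior, `run.observations` the harmonized records, and
`run.filter_report` the per-step accounting of excluded records.

The same pipeline runs from the shell:

```
morphotrend simulate --scenario beverly_adult_mass --seed 0 --out data/
morphotrend trajectory --surveys data/surveys.csv --span 0.75 --out traj.csv
morphotrend harmonize --records data/records.csv --trajectory traj.csv \
    --trait mass --out obs.csv
morphotrend fit --scenario beverly_adult_mass --seed 0 --out results/
morphotrend recover --preset rg_yearling_mass --replicates 20 --seed 0
```

`morphotrend fit` exits non-zero if any parameter has R̂ > 1.1.

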