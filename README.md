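# siteuse

Seasonal site-use models for opportunistic species records.

Volunteer reporting portals (GBIF-style species gateways) accumulate large
numbers of presence-only reports, but with no design: effort varies wildly
between observers, days, sites and years. `siteuse` estimates **daily**
site occupancy of a focal species from such records — and from the daily
states, the *seasonal site use*: the fraction of season days a site is
actually used. This resolves within-season dynamics (arrival, passage,
departure) that the conventional annual-closure occupancy model collapses
into a single "ever present this year" state, and it corrects for uneven
effort without any external effort measure.

It is aimed at ecologists analysing citizen-science bird/insect/plant
records, and at anyone who needs occupancy estimates at finer-than-season
resolution from presence-only data.

## The model

Nondetections are reconstructed from the reports themselves: each unique
observer reporting ≥ 1 study species at a site on a day is a replicate
*visit*, and a visit not listing the focal species is a nondetection. The
number of study species on the visit (species list length, SLL) proxies
effort.

For visit *j*, day *d*, year *t*, site *i*:

    y[j,d,t,i] ~ Bernoulli(u[d,t,i] · p[j,d,t,i])            (observation)
    u[d,t,i]   ~ Bernoulli(ψ[d,t,i])                         (occupancy)
    ψ[d,t,i]   = u[d−1]·φ[d−1,t,i] + (1−u[d−1])·γ[d−1,t,i]   (daily dynamics)

Persistence φ and colonization γ are probit-quadratic in the (standardized)
day of season with site and year random effects:

    probit(φ[d,t,i]) = pCoef1 + pCoef2·JDay[d] + pCoef3·JDay[d]² + ε_pI[i] + ε_pT[t]
    probit(γ[d,t,i]) = gCoef1 + gCoef2·JDay[d] + gCoef3·JDay[d]² + ε_gI[i] + ε_gT[t]

Detection saturates with list length,

    p[j,d,t,i] = SLL[j,d,t,i] / (SLL[j,d,t,i] + δ[t,i]),
    log(δ[t,i]) = dCoef1[i] + dCoef2 · PLL[t],

where δ is the list length at which detection reaches 0.5 and PLL[t] is the
annual proportion of long lists (SLL ≥ 10), absorbing drift in reporting
behaviour. Derived quantities are the seasonal site use
z[t,i] = Σ_d u[d,t,i] / n and its regional average Z[t].

Fitting is Bayesian MCMC: exact forward-filtering backward-sampling of the
latent daily chains, adaptive Metropolis for coefficients and random
effects, conjugate draws for day-1 occupancy and the random-effect
precisions (numba-accelerated). Goodness of fit comes from posterior
predictive checks with site-specific Bayesian p-values on sums of squared
Pearson-style residuals of annual site use. The package also ships the
annual-closure comparison model, and a scenario simulator for validation.

## Worked example

Simulate a medium-occupancy dataset (3 wetland sites, 3 years, 90-day
seasons) and refit it:

```python
from siteuse import (scenario_presets, simulate_dataset,
                     SeasonalSiteUseModel, MCMCConfig)

spec = scenario_presets()[2].with_dims(n_sites=3, n_years=3)
ds = simulate_dataset(spec, seed=1)

model = SeasonalSiteUseModel.from_records(
    ds.records, focal_species="focal", study_species=ds.study_species,
    season=ds.season)
res = model.fit(MCMCConfig(n_chains=2, n_burnin=1000, n_iter=3000, seed=1))
print(res.summary())
```

which prints (abridged):

```
Seasonal site-use model (daily dynamic occupancy)
==========================================================
focal species: focal
sites: 3  years: 3  days: 90  detections: 939
chains: 2  draws/chain: 3000

     parameter  median   mean     sd  ci2.5  ci97.5
        pCoef1   0.941  0.952  0.348  0.187   1.817
        gCoef1  -0.648 -0.692  0.324 -1.702  -0.206
        dCoef2  -1.352 -1.339  0.372 -2.039  -0.595
dCoef1[site_1]   1.539  1.531  0.156  1.227   1.814
...

Regional seasonal site use Z[t] (median [95% CI]):
  2005: 0.404 [0.378, 0.433]
  2006: 0.500 [0.485, 0.515]
  2007: 0.448 [0.437, 0.459]
```

The generating truth for this seed is `Z = (0.393, 0.500, 0.459)` — each
true value sits inside its 95% credible interval. `pCoef1`/`gCoef1` are the
probit intercepts of daily persistence/colonization; `dCoef1[site]` is the
log half-saturation list length per site (truth ≈ log 5 ≈ 1.61), and the
negative `dCoef2` says detection improves as long lists become more common.
A posterior predictive check

```python
rep = res.gof(seed=1)
print(rep.bayes_p)        # [0.66 0.7  0.66]
```

gives site-level Bayesian p-values near 0.5: no evidence of misfit.

The same pipeline is available from the shell:

```sh
siteuse simulate --scenario 2 --seed 1 --out sim/
siteuse fit --records sim/records.csv --focal focal --out fit/
siteuse validate --scenarios 1,2,3 --out val/
```

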