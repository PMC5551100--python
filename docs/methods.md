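# Methods

## Model

The package fits a two-level hidden Markov model per focal species. Within
each season (default 90 days) and site, the latent daily occupancy state
`u[d]` follows a Bernoulli chain whose transition rates — persistence `φ`
out of occupied days and colonization `γ` out of empty days — are probit
regressions on a quadratic of the day of season plus site and year random
effects. The quadratic lets occupancy rise, fall, or pulse within a season,
which covers residents, early/late breeders and passage migrants with one
parameterization. Conditional on presence, each visit detects the species
with probability `p = SLL/(SLL + δ)`: a saturating function of the visit's
species list length with half-saturation `δ`, so a single-species report
carries little nondetection evidence while a 30-species list carries a lot.
`log δ[t,i]` has a site intercept and a slope on the annual long-list
proportion `PLL[t]`, absorbing secular change in reporting habits.
Detection is constant within a season per (year, site) by design:
day-varying detection competes with the persistence/colonization curves for
the same within-season signal and is not jointly identifiable from
presence-only lists, so only the between-visit SLL effect and
between-year/site structure are modelled.

**Day-1 initial condition.** The daily recursion needs a start state that
the seasonal structure does not supply. Each (year, site) gets an explicit
initial occupancy probability `ψ₁[t,i]` with a Uniform(0,1) prior, updated
conjugately (Beta). This is deliberately agnostic: day-1 occupancy is then
informed almost entirely by the data near the season start.

**Day covariate.** The day-of-season covariate is centred and scaled (mean
0, SD 1 over the season) before entering the quadratic. A raw day-number
quadratic under a probit link puts the intercept hundreds of prior SDs from
the data's region and mixes catastrophically; the standardized form is the
same model with reparameterized coefficients, and the convention is
recorded in the model metadata (`standardized_jday`).

## Priors

Regression coefficients and random effects follow zero-centred Normals.
Two presets exist:

- `PriorSpec.vague()` — SD 1000 on effect parameters, Gamma(0.001, 0.001)
  on random-effect precisions (rate parameterization). This is the
  conventional flat choice, kept for fidelity to common practice.
- `PriorSpec.weakly_informative()` — SD 2.5 (the default). On a probit
  scale, Normal(0, 1000²) places almost all prior mass on rates
  indistinguishable from 0 or 1 and can stall adaptation; SD 2.5 covers
  every practically distinct rate while remaining diffuse.

All package defaults and the recovery experiments use the
weakly-informative preset; the vague preset is one constructor call away.

## Sampler

One Gibbs sweep:

1. **Latent chains** — exact joint draw of each site-year's `u` sequence by
   forward filtering / backward sampling (FFBS) on the 2-state chain. This
   is a correctness upgrade over single-site flip updates: the draw is from
   the exact conditional, so latent mixing is immediate.
2. **`ψ₁`** — conjugate Beta.
3. **Coefficients and random effects** — scalar adaptive random-walk
   Metropolis. Persistence terms of the process likelihood involve only
   transitions out of occupied days and colonization terms only transitions
   out of empty days, so the two blocks are evaluated (and updated)
   separately; site/year random-effect updates touch only their slice.
   Step sizes adapt towards 0.44 acceptance with a decaying gain and are
   frozen at the end of burn-in, so the post-burn-in kernel is a fixed,
   valid MCMC kernel.
4. **Precisions** — conjugate Gamma given the random effects.

Defaults: 3 chains, 5 000 burn-in, 15 000 kept iterations. Chains are
seeded deterministically from the run seed (`seed·9973 + 7919·chain + 1`,
mod 2³¹−1); a fixed seed reproduces every draw bit-for-bit. Convergence is
summarized by split-R̂ and ESS (via arviz) with a 1.1 flag threshold;
non-convergence warns but does not raise. Numerical guards: probabilities
clipped to [1e-12, 1−1e-12] inside log-likelihoods; the forward pass is
normalized per day in log space; impossible data (a detection under forced
absence) carry log-likelihood −1e30 rather than −∞ so the kernels stay
NaN-free.

The sampler refuses data with visits but zero detections (δ and ψ are then
jointly unidentifiable). A history with *no* visits at all is allowed and
yields prior draws — used to verify that the sampler's stationary
distribution for the effect coefficients is their prior.

## Ingest conventions

- A visit is one (observer, site, date) with ≥ 1 study-species report; SLL
  counts distinct *study* species only.
- At most 40 visits per site-day are kept (configurable), prioritizing the
  longest lists; ties at the boundary break by observer id ascending, so
  the filter is deterministic.
- `PLL[t]` = share of visits with SLL ≥ 10, pooled over sites.
- Day 1 is the season start; the season length is `n` days (default 90). A
  calendar window like April 1 – June 30 spans 91 days: records on days
  `n+1 … n+grace` are dropped with an explicit warning, never silently.
- Observers are matched by exact string identity; no fuzzy deduplication.

## Derived quantities and goodness of fit

Seasonal site use `z[t,i]` is the per-draw mean of `u` over days and `Z[t]`
its average over sites; summaries are the posterior median and central 95%
interval. Observed site use `w[t,i]` uses the daily maximum detection
status with *unvisited days counting 0* and the full season length `n` in
the denominator — the alternative (divide by visited days) is a different
statistic and is not used, so `w` is comparable with the model expectation
`w̄[t,i] = Σ_d u·(1−Π_j(1−p_j))/n`.

Posterior predictive checks replicate `y` under each retained draw with the
observed effort pattern held fixed, and compare discrepancies

    SSQ_i = Σ_t (w[t,i] − w̄[t,i])² / (w̄[t,i]·(1 − p̄[t,i])),

with `p̄[t,i]` the season mean of the daily at-least-one-detection
probability. The discrepancy can also be read with the square applied to
the whole ratio; both readings are implemented (`reading="pearson"`
default, `"literal"` optional) because the ratio form is ambiguous as
commonly typeset. Denominators are floored at 1e-12 and sites whose
expected site use is ~0 in every year are reported as "no information"
(p-value NaN, flagged) rather than as spurious extremes. The Bayesian
p-value per site is the fraction of draws whose replicated-data SSQ exceeds
the observed-data SSQ; values near 0.5 indicate adequate fit.

## Annual comparison model

The annual-closure model treats all long-list visits (SLL ≥ 10) of a season
as replicates of a single annual state `z[t,i]`, with scalar year-to-year
persistence/colonization under Uniform priors (conjugate Beta updates given
the latent states, FFBS over years per site) and the same SLL detection
curve (site intercepts by Metropolis). This is the minimal structure
consistent with the standard multi-season formulation; site effects enter
through detection. Annual "ever used" occupancy necessarily dominates mean
daily site use, which is the substantive contrast the package exposes via
`compare_models`.

## Simulator

The generator emulates portal-style sampling: for every site-day, a visit
count from a Poisson truncated to [1, 50] (so no missing days), with
among-site effort variability (log-normal site factor, SD 0.3); per-visit
list lengths from a single/short/long mixture — long weight equal to the
year's nominal long-list share (logistic rise 0.1 → 0.5 across years),
remaining mass split 70/30 between single reports and short (2–9) lists,
long lists 10 + geometric(0.25) capped at 45; detections thinned by the
saturation curve. Emitted records contain the focal species on detected
visits plus filler study species padding each list to its length, so the
ingest round trip reconstructs the generator's arrays exactly.

Generating constants for the nine scenarios: probit intercepts give
stationary daily occupancy ≈ 0.80 / 0.50 / 0.10 (high/medium/low);
occupancy-trend scenarios sweep both intercepts linearly by ±1.0 probit
units across years; visit-trend scenarios sweep the mean from 2 to 8 (or 8
to 2) visits per day; detectability-trend scenarios sweep `log δ` by ∓1
across years *outside* the fitted model's covariates, probing robustness.
Site/year random effects have SD 0.2; detection intercepts centre on
δ = 5 (SD 0.3 on the log scale) with PLL slope −1. A passage-migrant
preset concentrates colonization in a mid-season pulse
(`gCoef = (0.6, 0, −12)` on standardized days) with modest persistence, so
sites are used on ~10–20% of days but touched in almost every site-year.

What the simulator does *not* emulate: observer heterogeneity beyond list
length, non-independent visits (shared sightings), spatial correlation
between sites, day-of-week effort cycles, and true missing days (every
simulated site-day has ≥ 1 visit). Passing recovery tests therefore show
the estimator handles effort/reporting drift of the modelled kinds, not
that real portal data satisfy the model's independence assumptions.

## Problem sizes in the test battery

Recovery experiments run at 3 sites × 5 years × 90 days with 2 chains ×
3 000 kept iterations (1 000 burn-in), a size at which the nine-scenario
battery and the rest of the suite complete in a few minutes while intervals
are already narrow (typical 95% CI width for `Z[t]` ≈ 0.02–0.12).
Calibration replicates use 3 sites × 4 years with single chains. Full-size
runs (5–9 sites, 10 years, 3 × 20 000 iterations) use the same code path.

## Known limitations

- Individual probit coefficients and random-effect SDs can mix slowly on
  sparse data (few detections per site-year); the derived site-use
  quantities are far better identified than the coefficients themselves.
- The intercept and the random-effect means are only softly separated (by
  the zero-centred shrinkage priors), as in any centered hierarchical
  parameterization.
- Detection identifiability requires SLL variation; if every list had the
  same length, δ and occupancy would trade off freely.
- The within-season detection-trend hook (a day covariate on `log δ`) is
  deliberately not fitted; see the identifiability note above.
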