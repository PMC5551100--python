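import numpy as np
import pandas as pd
import pytest

from siteuse import (MISSING, DetectionHistory, ModelParams, SeasonWindow,
                     scenario_presets, simulate_dataset)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated dataset (scenario 2, 2 sites x 2 years x 30 days)."""
    spec = scenario_presets()[2].with_dims(n_sites=2, n_years=2, n_days=30)
    return simulate_dataset(spec, seed=42)


@pytest.fixture
def toy_records():
    """Hand-written record table: 2 sites, 1 year, a few days."""
    rows = [
        # day 3 at siteA: two observers
        ("sp1", "siteA", "2010-04-03", "alice"),
        ("sp2", "siteA", "2010-04-03", "alice"),
        ("sp1", "siteA", "2010-04-03", "bob"),
        # day 5 at siteA: single report
        ("sp3", "siteA", "2010-04-05", "alice"),
        # day 3 at siteB
        ("sp1", "siteB", "2010-04-03", "carol"),
        ("sp2", "siteB", "2010-04-03", "carol"),
        ("sp3", "siteB", "2010-04-03", "carol"),
    ]
    return pd.DataFrame(rows, columns=["species", "site", "date", "observer"])


def random_history(rng, n_days=6, n_years=1, n_sites=1, max_visits=3,
                   p_missing=0.3):
    """Random small DetectionHistory for oracle comparisons."""
    shape = (max_visits, n_days, n_years, n_sites)
    y = np.full(shape, MISSING, dtype=np.int8)
    sll = np.full(shape, np.nan)
    for d in range(n_days):
        for t in range(n_years):
            for i in range(n_sites):
                if rng.random() < p_missing:
                    continue
                nv = rng.integers(1, max_visits + 1)
                for j in range(nv):
                    y[j, d, t, i] = rng.integers(0, 2)
                    sll[j, d, t, i] = rng.integers(1, 20)
    return DetectionHistory(
        y=y, sll=sll, nvisits=(y != MISSING).sum(axis=0).astype(np.int32),
        pll=rng.uniform(0.05, 0.6, n_years), focal_species="focal",
        sites=[f"s{i}" for i in range(n_sites)],
        years=[2000 + t for t in range(n_years)],
        season=SeasonWindow(n_days=n_days),
    )


def brute_force_marginal(history, params, t, i):
    """Marginal log-likelihood of one site-year by exhaustive enumeration
    over all 2^n latent sequences (independent oracle for the forward
    algorithm; built from scalar primitives only)."""
    import itertools

    from siteuse import (day_obs_likelihood, detection_prob,
                         delta_from_covariates, seasonal_rate,
                         standardized_jday)

    n = history.n_days
    jday = standardized_jday(n).values
    delta = delta_from_covariates(params.dcoef1[i], params.dcoef2,
                                  history.pll[t])
    # per-day observation likelihoods for both latent states
    L = np.empty((n, 2))
    for d in range(n):
        ys = history.y[:, d, t, i]
        keep = ys != MISSING
        p = np.atleast_1d(detection_prob(history.sll[keep, d, t, i], delta))
        L[d, 0] = day_obs_likelihood(ys[keep], p, 0)
        L[d, 1] = day_obs_likelihood(ys[keep], p, 1)
    phi = [seasonal_rate(params.pcoef, jday[d], params.eps_p_site[i],
                         params.eps_p_year[t]) for d in range(n - 1)]
    gam = [seasonal_rate(params.gcoef, jday[d], params.eps_g_site[i],
                         params.eps_g_year[t]) for d in range(n - 1)]
    psi = params.psi1[t, i]
    total = 0.0
    for seq in itertools.product((0, 1), repeat=n):
        pr = psi if seq[0] else 1 - psi
        for d in range(1, n):
            rate = phi[d - 1] if seq[d - 1] else gam[d - 1]
            pr *= rate if seq[d] else 1 - rate
        for d in range(n):
            pr *= L[d, seq[d]]
        total += pr
    return np.log(total)


def random_params(rng, n_years=1, n_sites=1):
    return ModelParams(
        pcoef=rng.normal(0, 0.8, 3), gcoef=rng.normal(0, 0.8, 3),
        eps_p_site=rng.normal(0, 0.3, n_sites),
        eps_g_site=rng.normal(0, 0.3, n_sites),
        eps_p_year=rng.normal(0, 0.3, n_years),
        eps_g_year=rng.normal(0, 0.3, n_years),
        dcoef1=rng.normal(1.0, 0.5, n_sites), dcoef2=rng.normal(0, 0.5),
        psi1=rng.uniform(0.1, 0.9, (n_years, n_sites)),
    )
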