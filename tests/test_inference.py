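"""Posterior sampler: latent-state updates, determinism, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from siteuse import (MCMCConfig, PosteriorSamples, PriorSpec, SeasonWindow,
                     SeasonalSiteUseModel, check_convergence, detection_prob,
                     standardized_jday)
from siteuse.ingest import MISSING, DetectionHistory
from siteuse.likelihood import rate_curves, _day_logliks

from conftest import random_history, random_params


def exact_smoother(history, params, t=0, i=0):
    """Exact P(u_d = 1 | y, params) by forward-backward (independent oracle)."""
    n = history.n_days
    jday = standardized_jday(n)
    phi_a, gam_a = rate_curves(params, jday)
    phi, gam = phi_a[:, t, i], gam_a[:, t, i]
    delta = float(np.exp(params.dcoef1[i] + params.dcoef2 * history.pll[t]))
    logb0, logb1 = _day_logliks(history.y[:, :, t, i],
                                history.sll[:, :, t, i], delta)
    b0, b1 = np.exp(logb0), np.exp(np.clip(logb1, -700, 0))
    psi = params.psi1[t, i]
    fwd = np.zeros((n, 2))
    fwd[0] = [(1 - psi) * b0[0], psi * b1[0]]
    fwd[0] /= fwd[0].sum()
    for d in range(1, n):
        trans = np.array([[1 - gam[d - 1], gam[d - 1]],
                          [1 - phi[d - 1], phi[d - 1]]])
        v = fwd[d - 1] @ trans * np.array([b0[d], b1[d]])
        fwd[d] = v / v.sum()
    bwd = np.ones((n, 2))
    for d in range(n - 2, -1, -1):
        trans = np.array([[1 - gam[d], gam[d]], [1 - phi[d], phi[d]]])
        v = trans @ (np.array([b0[d + 1], b1[d + 1]]) * bwd[d + 1])
        bwd[d] = v / v.sum()
    post = fwd * bwd
    return post[:, 1] / post.sum(axis=1)


def _fit_latent_only(history, params, n_iter=4000, seed=5):
    model = SeasonalSiteUseModel(history)
    return model.fit(MCMCConfig(n_chains=1, n_burnin=1, n_iter=n_iter,
                                seed=seed),
                     update_params=False, start=params)


class TestLatentStateSampling:
    def test_detection_forces_presence(self):
        rng = np.random.default_rng(0)
        h = random_history(rng, n_days=6, p_missing=0.2)
        h.y[0, 2, 0, 0] = 1
        h.sll[0, 2, 0, 0] = 5
        h.nvisits = (h.y != MISSING).sum(axis=0).astype(np.int32)
        res = _fit_latent_only(h, random_params(rng), n_iter=200)
        assert (res.samples.flat_u()[:, 2, 0, 0] == 1).all()

    def test_absorbing_persistence(self):
        """phi=1, gamma=0, psi1=1 gives the all-ones latent sequence."""
        rng = np.random.default_rng(1)
        h = random_history(rng, n_days=6, p_missing=0.5)
        h.y[h.y == 1] = 0
        params = random_params(rng)
        params.pcoef[:] = [30.0, 0, 0]
        params.gcoef[:] = [-30.0, 0, 0]
        params.eps_p_site[:] = params.eps_p_year[:] = 0
        params.eps_g_site[:] = params.eps_g_year[:] = 0
        params.psi1[:] = 1.0 - 1e-12
        res = _fit_latent_only(h, params, n_iter=100)
        assert res.samples.flat_u().all()

    def test_perfect_detection_degeneracy(self):
        """p ~ 1 everywhere and no missing days: u equals the observed
        daily maximum detection exactly."""
        rng = np.random.default_rng(2)
        h = random_history(rng, n_days=8, p_missing=0.0, max_visits=2)
        h.sll[~np.isnan(h.sll)] = 1e9
        params = random_params(rng)
        params.dcoef1[:] = 0.0
        params.dcoef2 = 0.0
        res = _fit_latent_only(h, params, n_iter=300)
        observed = (h.y == 1).any(axis=0).astype(int)
        u = res.samples.flat_u()
        assert (u == observed[None, ...]).all()

    def test_ffbs_marginals_match_exact_smoother(self):
        """Empirical mean of repeated joint draws equals the exact
        forward-backward smoothed probabilities."""
        rng = np.random.default_rng(3)
        h = random_history(rng, n_days=5, p_missing=0.25, max_visits=3)
        params = random_params(rng)
        res = _fit_latent_only(h, params, n_iter=10000)
        emp = res.samples.flat_u()[:, :, 0, 0].mean(axis=0)
        exact = exact_smoother(h, params)
        assert np.max(np.abs(emp - exact)) < 0.02


class TestSamplerContracts:
    def test_same_seed_identical_draws(self, tiny_dataset):
        ds = tiny_dataset
        model = SeasonalSiteUseModel.from_records(
            ds.records, ds.focal_species, ds.study_species, season=ds.season)
        cfg = MCMCConfig(n_chains=1, n_burnin=50, n_iter=100, seed=99)
        r1 = model.fit(cfg)
        r2 = model.fit(cfg)
        for key in r1.samples.params:
            np.testing.assert_array_equal(r1.samples.params[key],
                                          r2.samples.params[key])
        np.testing.assert_array_equal(r1.samples.u, r2.samples.u)

    def test_zero_detections_refused(self):
        rng = np.random.default_rng(4)
        h = random_history(rng, n_days=6)
        h.y[h.y == 1] = 0
        model = SeasonalSiteUseModel(h)
        with pytest.raises(ValueError, match="unidentifiable"):
            model.fit(MCMCConfig(n_chains=1, n_burnin=10, n_iter=10, seed=0))

    def test_prior_only_run_recovers_prior_sd(self):
        """With no visits at all the sampler's stationary distribution for
        the effect coefficients is their Normal prior."""
        shape = (1, 20, 1, 1)
        h = DetectionHistory(
            y=np.full(shape, MISSING, dtype=np.int8),
            sll=np.full(shape, np.nan),
            nvisits=np.zeros(shape[1:], dtype=np.int32),
            pll=np.array([0.2]), focal_species="focal", sites=["s"],
            years=[2000], season=SeasonWindow(n_days=20))
        model = SeasonalSiteUseModel(h, priors=PriorSpec(effect_sd=2.5))
        res = model.fit(MCMCConfig(n_chains=1, n_burnin=2000, n_iter=10000,
                                   seed=8))
        for key in ("pcoef", "gcoef", "dcoef1"):
            draws = res.samples.flat(key)
            sds = draws.reshape(draws.shape[0], -1).std(axis=0)
            assert np.all(np.abs(sds - 2.5) / 2.5 < 0.10), (key, sds)

    def test_posterior_samples_save_load(self, tiny_dataset, tmp_path):
        ds = tiny_dataset
        model = SeasonalSiteUseModel.from_records(
            ds.records, ds.focal_species, ds.study_species, season=ds.season)
        res = model.fit(MCMCConfig(n_chains=1, n_burnin=20, n_iter=50, seed=1))
        res.samples.save(tmp_path / "s")
        back = PosteriorSamples.load(tmp_path / "s")
        np.testing.assert_array_equal(back.u, res.samples.u)
        np.testing.assert_allclose(back.params["pcoef"],
                                   res.samples.params["pcoef"])


class TestConvergenceDiagnostics:
    @staticmethod
    def _samples_from(chains_dict, n_chains, n_draws):
        params = {
            "pcoef": np.zeros((n_chains, n_draws, 3)),
            "gcoef": np.zeros((n_chains, n_draws, 3)),
            "eps_p_site": np.zeros((n_chains, n_draws, 1)),
            "eps_g_site": np.zeros((n_chains, n_draws, 1)),
            "eps_p_year": np.zeros((n_chains, n_draws, 1)),
            "eps_g_year": np.zeros((n_chains, n_draws, 1)),
            "dcoef1": np.zeros((n_chains, n_draws, 1)),
            "dcoef2": chains_dict,
            "psi1": np.zeros((n_chains, n_draws, 1, 1)),
            "sigma": np.ones((n_chains, n_draws, 4)),
        }
        u = np.zeros((n_chains, n_draws, 2, 1, 1), dtype=np.uint8)
        return PosteriorSamples(params=params, u=u,
                                accept_rates=np.zeros((n_chains, 1)))

    def test_well_mixed_chain_split_has_rhat_near_one(self):
        rng = np.random.default_rng(0)
        long = rng.normal(size=4000)
        s = self._samples_from(long.reshape(2, 2000), 2, 2000)
        row = check_convergence(s).set_index("parameter").loc["dcoef2"]
        assert abs(row["rhat"] - 1.0) < 0.01 and not row["flagged"]

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        c = np.stack([rng.normal(0, 0.1, 1000), rng.normal(5, 0.1, 1000)])
        s = self._samples_from(c, 2, 1000)
        row = check_convergence(s).set_index("parameter").loc["dcoef2"]
        assert row["rhat"] > 1.5 and bool(row["flagged"])

    def test_white_noise_ess_close_to_n(self):
        rng = np.random.default_rng(2)
        n = 4000
        s = self._samples_from(rng.normal(size=(2, n // 2)), 2, n // 2)
        row = check_convergence(s).set_index("parameter").loc["dcoef2"]
        assert abs(row["ess"] - n) / n < 0.20

    def test_single_chain_reports_ess_only(self):
        rng = np.random.default_rng(3)
        s = self._samples_from(rng.normal(size=(1, 500)), 1, 500)
        out = check_convergence(s)
        assert out["rhat"].isna().all()
        assert (out["ess"] > 0).all()


def test_wider_effort_shrinks_interval(tiny_dataset):
    """More visits with longer lists yield tighter site-use intervals."""
    from siteuse import scenario_presets, simulate_dataset

    spec_rich = scenario_presets()[2].with_dims(n_sites=2, n_years=2,
                                                n_days=30)
    ds_rich = simulate_dataset(spec_rich, seed=5)
    # impoverished copy: keep only the single longest-list visit per day
    from siteuse import build_visits, build_detection_history, cap_visits

    v = build_visits(ds_rich.records, ds_rich.season, ds_rich.study_species)
    cfg = MCMCConfig(n_chains=1, n_burnin=300, n_iter=800, seed=2)
    widths = []
    for cap in (50, 1):
        capped = cap_visits(v, cap)
        h = build_detection_history(capped, ds_rich.focal_species,
                                    ds_rich.study_species, ds_rich.season,
                                    max_visits=cap)
        res = SeasonalSiteUseModel(h).fit(cfg)
        su = res.site_use()
        widths.append(float(np.mean(su.Z_hi - su.Z_lo)))
    assert widths[0] < widths[1]
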