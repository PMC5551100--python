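"""Comparison model: multi-season (annual-closure) dynamic occupancy.

The conventional approach for opportunistic data treats the whole season as
one closed period: a site is "occupied" in a year if the species used it at
all, and all (long-list) visits of the season are replicates.  Annual
occupancy states follow a year-to-year chain with scalar persistence and
colonization, and detection shares the list-length saturation curve of the
daily model.  Because "occupied at annual closure" means "present on at
least one day", annual occupancy systematically exceeds mean daily site use
for species with temporary within-season occurrence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import MISSING, DetectionHistory
from .derived import SiteUseSummary
from .model import MCMCConfig, PriorSpec

__all__ = ["AnnualHistory", "AnnualOccupancyModel", "AnnualOccupancyResults",
           "build_annual_history", "compare_models"]


@dataclass
class AnnualHistory:
    """Within-season replicate visits under a whole-season closure.

    ``y[v, t, i]`` stacks the retained (long-list) visits of each site-year;
    slots beyond a site-year's visit count are :data:`MISSING`.
    """

    y: np.ndarray            # int8 (V, T, I)
    sll: np.ndarray          # float64, NaN where missing
    pll: np.ndarray          # (T,)
    focal_species: str
    sites: list = field(default_factory=list)
    years: list = field(default_factory=list)
    long_threshold: int = 10

    @property
    def n_years(self):
        return self.y.shape[1]

    @property
    def n_sites(self):
        return self.y.shape[2]


def build_annual_history(visits: pd.DataFrame, focal_species: str,
                         long_threshold: int = 10,
                         sites=None, years=None,
                         pll: np.ndarray | None = None) -> AnnualHistory:
    """Stack all long-list visits of each site-year as annual replicates.

    ``pll`` defaults to the long-list proportion computed from the *full*
    visit table (before thresholding), matching the covariate the daily
    model uses.
    """
    from .ingest import compute_pll

    if pll is None:
        pll_series = compute_pll(visits, long_threshold=long_threshold)
    sites = sorted(visits["site"].unique()) if sites is None else list(sites)
    years = sorted(visits["year"].unique()) if years is None else list(years)
    keep = visits[visits["sll"] >= long_threshold]
    site_ix = {s: k for k, s in enumerate(sites)}
    year_ix = {y: k for k, y in enumerate(years)}

    counts = keep.groupby(["site", "year"]).size()
    V = int(counts.max()) if len(counts) else 1
    y = np.full((V, len(years), len(sites)), MISSING, dtype=np.int8)
    sll = np.full((V, len(years), len(sites)), np.nan)
    ordered = keep.sort_values(["site", "year", "day", "sll", "observer"],
                               ascending=[True, True, True, False, True],
                               kind="stable")
    slot = ordered.groupby(["site", "year"], sort=False).cumcount()
    for row, v in zip(ordered.itertuples(index=False), slot):
        t, i = year_ix[row.year], site_ix[row.site]
        y[v, t, i] = 1 if focal_species in row.species_set else 0
        sll[v, t, i] = row.sll
    if pll is None:
        pll = pll_series.reindex(years).fillna(0.0).to_numpy(float)
    return AnnualHistory(y=y, sll=sll, pll=np.asarray(pll, float),
                         focal_species=focal_species, sites=sites,
                         years=years, long_threshold=long_threshold)


@dataclass
class AnnualEstimates:
    """Posterior draws from the annual model (all arrays draw-indexed)."""

    z: np.ndarray              # (n, T, I) latent annual occupancy states
    psi_regional: np.ndarray   # (n, T) mean occupancy over sites
    phi_year: np.ndarray       # (n,) year-to-year persistence
    gamma_year: np.ndarray     # (n,)
    dcoef1: np.ndarray         # (n, I)
    dcoef2: np.ndarray         # (n,)
    sites: list = field(default_factory=list)
    years: list = field(default_factory=list)

    def occupancy_median(self) -> np.ndarray:
        return np.median(self.psi_regional, axis=0)

    def occupancy_ci(self):
        return (np.percentile(self.psi_regional, 2.5, axis=0),
                np.percentile(self.psi_regional, 97.5, axis=0))


class AnnualOccupancyModel:
    """Annual-closure dynamic occupancy model on long-list visits.

    Latent annual states z[t, i] follow z[1] ~ Bernoulli(psi1) and
    z[t] ~ Bernoulli(z[t-1] * phi + (1 - z[t-1]) * gamma) with scalar
    year-to-year rates under Uniform(0, 1) priors (conjugate Beta updates
    given the latent states); per-visit detection uses the shared
    list-length curve with site intercepts updated by random-walk
    Metropolis.
    """

    def __init__(self, history: AnnualHistory, priors: PriorSpec | None = None):
        self.history = history
        self.priors = priors if priors is not None else PriorSpec()

    def fit(self, config: MCMCConfig | None = None) -> "AnnualOccupancyResults":
        config = config if config is not None else MCMCConfig(
            n_chains=2, n_burnin=1000, n_iter=3000)
        h = self.history
        if (h.y == 1).sum() == 0:
            raise ValueError("no detections on long-list visits")
        draws = []
        for c in range(config.n_chains):
            draws.append(self._run_chain(config, config.chain_seed(c)))
        est = AnnualEstimates(
            z=np.concatenate([d["z"] for d in draws]),
            psi_regional=np.concatenate([d["psi_regional"] for d in draws]),
            phi_year=np.concatenate([d["phi"] for d in draws]),
            gamma_year=np.concatenate([d["gamma"] for d in draws]),
            dcoef1=np.concatenate([d["dcoef1"] for d in draws]),
            dcoef2=np.concatenate([d["dcoef2"] for d in draws]),
            sites=list(h.sites), years=list(h.years),
        )
        return AnnualOccupancyResults(self, est, config)

    # -- internals --------------------------------------------------------

    def _obs_loglik(self, d1, d2):
        """log P(y[v,t,i] | z=1) per (t, i); z=0 forces all-zero visits."""
        h = self.history
        delta = np.exp(d1[None, :] + d2 * h.pll[:, None])     # (T, I)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = h.sll / (h.sll + delta[None, :, :])
            p = np.clip(p, 1e-12, 1 - 1e-12)
            terms = np.where(h.y == 1, np.log(p), np.log1p(-p))
        terms = np.where(np.isnan(h.sll), 0.0, terms)
        return terms.sum(axis=0)                              # (T, I)

    def _run_chain(self, config: MCMCConfig, seed: int) -> dict:
        h = self.history
        rng = np.random.default_rng(seed)
        T, I = h.n_years, h.n_sites
        any_det = (h.y == 1).any(axis=0)                      # (T, I)
        n_eff_sd = self.priors.effect_sd

        z = any_det.astype(np.int8).copy()
        phi, gamma, psi1 = 0.5, 0.5, 0.5
        d1 = np.full(I, math.log(3.0)) + rng.normal(0, 0.1, I)
        d2 = 0.0
        step = np.full(I + 1, 0.3)
        keep = []
        n_total = config.n_burnin + config.n_iter
        for sweep in range(n_total):
            ll1 = self._obs_loglik(d1, d2)                    # (T, I)
            # FFBS over years, per site
            for i in range(I):
                la0 = np.empty(T)
                la1 = np.empty(T)
                la0[0] = math.log(1 - psi1) + (0.0 if not any_det[0, i] else -np.inf)
                la1[0] = math.log(psi1) + ll1[0, i]
                for t in range(1, T):
                    b0 = 0.0 if not any_det[t, i] else -np.inf
                    la0[t] = np.logaddexp(la0[t - 1] + math.log(1 - gamma),
                                          la1[t - 1] + math.log(1 - phi)) + b0
                    la1[t] = np.logaddexp(la0[t - 1] + math.log(gamma),
                                          la1[t - 1] + math.log(phi)) + ll1[t, i]
                    m = max(la0[t], la1[t])
                    la0[t] -= m
                    la1[t] -= m
                z[T - 1, i] = rng.random() < 1 / (1 + np.exp(la0[T - 1] - la1[T - 1]))
                for t in range(T - 2, -1, -1):
                    if z[t + 1, i] == 1:
                        w0, w1 = la0[t] + math.log(gamma), la1[t] + math.log(phi)
                    else:
                        w0 = la0[t] + math.log(1 - gamma)
                        w1 = la1[t] + math.log(1 - phi)
                    z[t, i] = rng.random() < 1 / (1 + np.exp(w0 - w1))
            # conjugate Beta updates for the year-to-year rates
            prev, curr = z[:-1], z[1:]
            n11 = int(((prev == 1) & (curr == 1)).sum())
            n10 = int(((prev == 1) & (curr == 0)).sum())
            n01 = int(((prev == 0) & (curr == 1)).sum())
            n00 = int(((prev == 0) & (curr == 0)).sum())
            phi = float(np.clip(rng.beta(1 + n11, 1 + n10), 1e-6, 1 - 1e-6))
            gamma = float(np.clip(rng.beta(1 + n01, 1 + n00), 1e-6, 1 - 1e-6))
            k1 = int(z[0].sum())
            psi1 = float(np.clip(rng.beta(1 + k1, 1 + I - k1), 1e-6, 1 - 1e-6))
            # Metropolis for detection coefficients (occupied cells only)
            zmask = z.astype(bool)
            cur_ll = float(self._obs_loglik(d1, d2)[zmask].sum())
            for k in range(I):
                old = d1[k]
                d1[k] = old + rng.normal() * step[k]
                new_ll = float(self._obs_loglik(d1, d2)[zmask].sum())
                lr = (new_ll - cur_ll
                      - 0.5 * (d1[k] ** 2 - old ** 2) / n_eff_sd ** 2)
                if math.log(rng.random() + 1e-300) < lr:
                    cur_ll = new_ll
                else:
                    d1[k] = old
            old = d2
            d2 = old + rng.normal() * step[I]
            new_ll = float(self._obs_loglik(d1, d2)[zmask].sum())
            lr = new_ll - cur_ll - 0.5 * (d2 ** 2 - old ** 2) / n_eff_sd ** 2
            if not math.log(rng.random() + 1e-300) < lr:
                d2 = old
            if sweep >= config.n_burnin and (sweep - config.n_burnin) % config.thin == 0:
                keep.append((z.copy(), phi, gamma, d1.copy(), d2))
        return {
            "z": np.stack([k[0] for k in keep]),
            "psi_regional": np.stack([k[0].mean(axis=1) for k in keep]),
            "phi": np.array([k[1] for k in keep]),
            "gamma": np.array([k[2] for k in keep]),
            "dcoef1": np.stack([k[3] for k in keep]),
            "dcoef2": np.array([k[4] for k in keep]),
        }


class AnnualOccupancyResults:
    """Posterior summaries for the annual-closure model."""

    def __init__(self, model: AnnualOccupancyModel, estimates: AnnualEstimates,
                 config: MCMCConfig):
        self.model = model
        self.estimates = estimates
        self.config = config

    def summary_frame(self) -> pd.DataFrame:
        est = self.estimates
        lo, hi = est.occupancy_ci()
        return pd.DataFrame({
            "year": est.years,
            "occupancy_median": est.occupancy_median(),
            "ci2.5": lo, "ci97.5": hi,
        })

    def summary(self) -> str:
        est = self.estimates
        lines = ["Annual-closure dynamic occupancy model",
                 "=" * 44,
                 f"phi (year-to-year persistence): "
                 f"{np.median(est.phi_year):.3f}",
                 f"gamma (year-to-year colonization): "
                 f"{np.median(est.gamma_year):.3f}",
                 "",
                 self.summary_frame().to_string(index=False)]
        return "\n".join(lines)


def compare_models(annual: AnnualOccupancyResults,
                   daily: SiteUseSummary, years=None) -> pd.DataFrame:
    """Per-year contrast of annual occupancy vs. mean daily site use.

    Returns medians of both statistics, their difference, and whether the
    95% intervals overlap.  The two fits must cover the same year grid.
    """
    est = annual.estimates
    T_daily = daily.Z_median.shape[0]
    if len(est.years) != T_daily:
        raise ValueError(
            f"year grids differ: annual model has {len(est.years)} years, "
            f"daily model has {T_daily}")
    lo_a, hi_a = est.occupancy_ci()
    rows = pd.DataFrame({
        "year": years if years is not None else est.years,
        "annual_occupancy": est.occupancy_median(),
        "seasonal_site_use": daily.Z_median,
        "difference": est.occupancy_median() - daily.Z_median,
        "ci_overlap": ~((hi_a < daily.Z_lo) | (daily.Z_hi < lo_a)),
    })
    return rows
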