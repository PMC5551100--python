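"""Model/results objects for fitting the seasonal site-use model.

Usage follows the familiar build-then-fit pattern::

    model = SeasonalSiteUseModel.from_records(records, focal_species="focal",
                                              study_species=species)
    res = model.fit(MCMCConfig(n_chains=2, n_burnin=1000, n_iter=2000, seed=7))
    print(res.summary())
    res.site_use()          # posterior seasonal site use z[t,i], Z[t]
    res.gof(seed=1)         # posterior predictive check

The posterior is explored by Markov chain Monte Carlo: forward-filtering
backward-sampling for the latent daily occupancy chains, adaptive
random-walk Metropolis for regression coefficients and random effects, and
conjugate draws for the day-1 occupancy probabilities and random-effect
precisions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (DetectionHistory, SeasonWindow, build_visits, cap_visits,
                     build_detection_history)
from .likelihood import ModelParams, standardized_jday, total_loglik

__all__ = ["PriorSpec", "MCMCConfig", "PosteriorSamples",
           "SeasonalSiteUseModel", "SeasonalSiteUseResults",
           "check_convergence"]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: zero-centred Normals on regression coefficients (SD
    ``effect_sd``) and Gamma(shape, rate) on random-effect precisions.

    :meth:`vague` reproduces the conventional flat choice (SD 1000,
    Gamma(0.001, 0.001)).  On a probit scale an SD-1000 Normal puts almost
    all mass on rates of exactly 0 or 1, which can stall mixing, so
    :meth:`weakly_informative` (SD 2.5) is the default.
    """

    effect_sd: float = 2.5
    precision_shape: float = 0.001
    precision_rate: float = 0.001

    def __post_init__(self):
        if min(self.effect_sd, self.precision_shape, self.precision_rate) <= 0:
            raise ValueError("prior hyperparameters must be positive")

    @classmethod
    def vague(cls) -> "PriorSpec":
        return cls(effect_sd=1000.0)

    @classmethod
    def weakly_informative(cls) -> "PriorSpec":
        return cls(effect_sd=2.5)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run lengths: ``n_iter`` post-burn-in sweeps are kept (every
    ``thin``-th), after ``n_burnin`` adaptation sweeps, in each of
    ``n_chains`` chains.  A fixed ``seed`` makes runs bit-reproducible."""

    n_chains: int = 3
    n_burnin: int = 5000
    n_iter: int = 15000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chains, self.n_burnin, self.n_iter, self.thin) < 1:
            raise ValueError("chain counts, iterations and thinning must be >= 1")

    def chain_seed(self, chain: int) -> int:
        return int((self.seed * 9973 + 7919 * chain + 1) % (2 ** 31 - 1))


_PARAM_KEYS = ("pcoef", "gcoef", "eps_p_site", "eps_g_site", "eps_p_year",
               "eps_g_year", "dcoef1", "dcoef2", "psi1", "sigma")
_SIGMA_NAMES = ("sigma_p_site", "sigma_g_site", "sigma_p_year", "sigma_g_year")


@dataclass
class PosteriorSamples:
    """Stacked MCMC draws; every array is indexed (chain, draw, ...).

    ``params`` maps parameter names to arrays; ``u`` holds the latent daily
    occupancy draws with trailing dims (day, year, site).
    """

    params: dict
    u: np.ndarray                      # uint8 (chain, draw, D, T, I)
    accept_rates: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.u.shape[0]

    @property
    def n_draws(self) -> int:
        return self.u.shape[1]

    def flat(self, key: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated."""
        a = self.params[key]
        return a.reshape((-1,) + a.shape[2:])

    def flat_u(self) -> np.ndarray:
        return self.u.reshape((-1,) + self.u.shape[2:])

    def param_draw(self, chain: int, draw: int, history: DetectionHistory
                   ) -> ModelParams:
        p = self.params
        sig = p["sigma"][chain, draw]
        return ModelParams(
            pcoef=p["pcoef"][chain, draw], gcoef=p["gcoef"][chain, draw],
            eps_p_site=p["eps_p_site"][chain, draw],
            eps_g_site=p["eps_g_site"][chain, draw],
            eps_p_year=p["eps_p_year"][chain, draw],
            eps_g_year=p["eps_g_year"][chain, draw],
            dcoef1=p["dcoef1"][chain, draw],
            dcoef2=float(p["dcoef2"][chain, draw]),
            psi1=p["psi1"][chain, draw],
            sigma_p_site=float(sig[0]), sigma_g_site=float(sig[1]),
            sigma_p_year=float(sig[2]), sigma_g_year=float(sig[3]),
        )

    def to_inference_data(self):
        """Convert parameter draws to an :class:`arviz.InferenceData`."""
        import arviz as az

        data = {}
        for key, arr in self.params.items():
            if key == "sigma":
                for q, name in enumerate(_SIGMA_NAMES):
                    data[name] = arr[:, :, q]
            else:
                data[key] = arr
        return az.from_dict(posterior=data)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "draws.npz", u=self.u,
                            accept_rates=self.accept_rates,
                            **{k: v for k, v in self.params.items()})
        (directory / "samples.json").write_text(
            json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        with np.load(directory / "draws.npz") as z:
            params = {k: z[k] for k in _PARAM_KEYS}
            u = z["u"]
            acc = z["accept_rates"]
        meta = json.loads((directory / "samples.json").read_text())
        return cls(params=params, u=u, accept_rates=acc, meta=meta)


def check_convergence(samples: PosteriorSamples, rhat_limit: float = 1.1
                      ) -> pd.DataFrame:
    """Split-R̂ and effective sample size per scalar parameter.

    With a single chain R̂ is unavailable and only ESS is reported.
    Parameters with R̂ above ``rhat_limit`` are flagged.
    """
    import arviz as az

    idata = samples.to_inference_data()
    ess = az.ess(idata)
    rows = []
    rhat = az.rhat(idata) if samples.n_chains >= 2 else None
    for var in idata.posterior.data_vars:
        e = np.atleast_1d(ess[var].values).ravel()
        r = (np.atleast_1d(rhat[var].values).ravel()
             if rhat is not None else np.full(e.shape, np.nan))
        for k, (ev, rv) in enumerate(zip(e, r)):
            name = var if e.size == 1 else f"{var}[{k}]"
            rows.append((name, float(rv), float(ev)))
    out = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    out["flagged"] = out["rhat"] > rhat_limit
    return out


class SeasonalSiteUseModel:
    """Daily dynamic occupancy model for opportunistic records.

    Parameters
    ----------
    history : DetectionHistory
        Replicated detection/nondetection data for one focal species.
    priors : PriorSpec, optional
        Defaults to the weakly-informative choice.
    """

    def __init__(self, history: DetectionHistory, priors: PriorSpec | None = None):
        history.validate()
        self.history = history
        self.priors = priors if priors is not None else PriorSpec()
        self.jday = standardized_jday(history.n_days)

    @classmethod
    def from_records(cls, records: pd.DataFrame, focal_species: str,
                     study_species, season: SeasonWindow | None = None,
                     max_visits: int = 40, long_threshold: int = 10,
                     priors: PriorSpec | None = None,
                     sites=None, years=None) -> "SeasonalSiteUseModel":
        """Build the model straight from a raw record table."""
        season = season if season is not None else SeasonWindow()
        visits = build_visits(records, season, study_species)
        visits = cap_visits(visits, max_visits)
        history = build_detection_history(
            visits, focal_species, study_species, season,
            long_threshold=long_threshold, max_visits=max_visits,
            sites=sites, years=years)
        return cls(history, priors=priors)

    def loglike(self, params: ModelParams) -> float:
        """Marginal log-likelihood with latent states summed out."""
        return total_loglik(self.history, params, self.jday)

    def _initial_values(self, rng: np.random.Generator, jitter: float):
        h = self.history
        T, I = h.n_years, h.n_sites
        naive = (h.y == 1).any(axis=0).mean()
        base_d1 = np.log(3.0)
        init = dict(
            pc=np.array([0.5, 0.0, 0.0]), gc=np.array([-0.5, 0.0, 0.0]),
            epI=np.zeros(I), egI=np.zeros(I), epT=np.zeros(T),
            egT=np.zeros(T), d1=np.full(I, base_d1), d2=np.array([0.0]),
            psi1=np.full((T, I), min(max(naive, 0.05), 0.95)),
        )
        if jitter > 0:
            for key in ("pc", "gc", "d1", "d2"):
                init[key] = init[key] + rng.normal(0, jitter, init[key].shape)
            init["psi1"] = np.clip(
                init["psi1"] + rng.normal(0, jitter / 4, (T, I)), 0.02, 0.98)
        return init

    def fit(self, config: MCMCConfig | None = None,
            update_params: bool = True,
            start: ModelParams | None = None) -> "SeasonalSiteUseResults":
        """Draw from the posterior and wrap the draws in a results object.

        ``update_params=False`` freezes every parameter at its starting
        value (which must then be supplied via ``start``) and samples only
        the latent occupancy chains — useful for validating the latent-state
        update against exact smoothing.
        """
        from . import _sampler

        config = config if config is not None else MCMCConfig()
        h = self.history
        from .ingest import MISSING as _MISSING
        if (update_params and h.n_detections() == 0
                and (h.y != _MISSING).any()):
            raise ValueError(
                "no detections of the focal species: detection and occupancy "
                "parameters are unidentifiable")
        if not update_params and start is None:
            raise ValueError("update_params=False requires explicit start values")

        y = np.ascontiguousarray(h.y)
        sll = np.nan_to_num(h.sll, nan=0.0)
        pll = np.asarray(h.pll, float)
        jd = self.jday.values

        chains = {k: [] for k in _PARAM_KEYS}
        u_chains, acc_chains = [], []
        for c in range(config.n_chains):
            rng = np.random.default_rng(config.chain_seed(c))
            if start is not None:
                init = dict(
                    pc=start.pcoef.copy(), gc=start.gcoef.copy(),
                    epI=start.eps_p_site.copy(), egI=start.eps_g_site.copy(),
                    epT=start.eps_p_year.copy(), egT=start.eps_g_year.copy(),
                    d1=start.dcoef1.copy(), d2=np.array([start.dcoef2]),
                    psi1=start.psi1.copy(),
                )
            else:
                init = self._initial_values(rng, jitter=0.25 if c else 0.0)
            out = _sampler.run_chain(
                y, sll, pll, jd,
                self.priors.effect_sd, self.priors.precision_shape,
                self.priors.precision_rate,
                config.n_burnin, config.n_iter, config.thin,
                config.chain_seed(c),
                init["pc"], init["gc"], init["epI"], init["egI"],
                init["epT"], init["egT"], init["d1"], init["d2"],
                np.asarray(init["psi1"], float),
                update_params, True)
            (pc_o, gc_o, epI_o, egI_o, epT_o, egT_o, d1_o, d2_o, psi1_o,
             sig_o, u_o, rate) = out
            for key, arr in zip(_PARAM_KEYS, (pc_o, gc_o, epI_o, egI_o,
                                              epT_o, egT_o, d1_o, d2_o,
                                              psi1_o, sig_o)):
                chains[key].append(arr)
            u_chains.append(u_o)
            acc_chains.append(rate)

        params = {k: np.stack(v) for k, v in chains.items()}
        data_hash = hashlib.sha256(y.tobytes() + sll.tobytes()).hexdigest()[:16]
        samples = PosteriorSamples(
            params=params, u=np.stack(u_chains),
            accept_rates=np.stack(acc_chains),
            meta={"config": asdict(config), "priors": asdict(self.priors),
                  "data_hash": data_hash, "update_params": update_params,
                  "focal_species": h.focal_species},
        )
        return SeasonalSiteUseResults(self, samples, config)


class SeasonalSiteUseResults:
    """Posterior draws plus derived summaries for a fitted model."""

    def __init__(self, model: SeasonalSiteUseModel, samples: PosteriorSamples,
                 config: MCMCConfig):
        self.model = model
        self.samples = samples
        self.config = config
        self._convergence = None
        if (samples.n_chains >= 2 and samples.n_draws >= 100
                and samples.meta.get("update_params", True)):
            conv = self.convergence()
            n_bad = int(conv["flagged"].sum())
            if n_bad:
                warnings.warn(
                    f"{n_bad} parameter(s) have split-Rhat > 1.1; "
                    "consider longer chains", stacklevel=2)

    @property
    def history(self) -> DetectionHistory:
        return self.model.history

    def convergence(self) -> pd.DataFrame:
        if self._convergence is None:
            self._convergence = check_convergence(self.samples)
        return self._convergence

    def site_use(self):
        """Posterior seasonal site use per site-year (z) and region (Z)."""
        from .derived import site_use

        return site_use(self.samples.flat_u())

    def gof(self, seed: int = 0, n_rep: int | None = 400, reading: str = "pearson"):
        """Posterior predictive goodness-of-fit report."""
        from .gof import gof_report

        return gof_report(self, seed=seed, n_rep=n_rep, reading=reading)

    def posterior_mean_params(self) -> ModelParams:
        s = self.samples
        mean = {k: s.flat(k).mean(axis=0) for k in _PARAM_KEYS}
        sig = mean["sigma"]
        return ModelParams(
            pcoef=mean["pcoef"], gcoef=mean["gcoef"],
            eps_p_site=mean["eps_p_site"], eps_g_site=mean["eps_g_site"],
            eps_p_year=mean["eps_p_year"], eps_g_year=mean["eps_g_year"],
            dcoef1=mean["dcoef1"], dcoef2=float(mean["dcoef2"]),
            psi1=np.clip(mean["psi1"], 0, 1),
            sigma_p_site=float(sig[0]), sigma_g_site=float(sig[1]),
            sigma_p_year=float(sig[2]), sigma_g_year=float(sig[3]),
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        labels = {
            "pcoef": ["pCoef1", "pCoef2", "pCoef3"],
            "gcoef": ["gCoef1", "gCoef2", "gCoef3"],
            "dcoef2": ["dCoef2"],
            "sigma": list(_SIGMA_NAMES),
        }
        labels["dcoef1"] = [f"dCoef1[{s}]" for s in self.history.sites]
        for key, names in labels.items():
            draws = self.samples.flat(key)
            draws = draws.reshape(draws.shape[0], -1)
            for k, name in enumerate(names):
                col = draws[:, k]
                rows.append((name, np.median(col), col.mean(), col.std(),
                             np.percentile(col, 2.5), np.percentile(col, 97.5)))
        return pd.DataFrame(
            rows, columns=["parameter", "median", "mean", "sd",
                           "ci2.5", "ci97.5"])

    def summary(self) -> str:
        h = self.history
        su = self.site_use()
        frame = self.summary_frame()
        lines = [
            "Seasonal site-use model (daily dynamic occupancy)",
            "=" * 58,
            f"focal species: {h.focal_species}",
            f"sites: {h.n_sites}  years: {h.n_years}  days: {h.n_days}"
            f"  detections: {h.n_detections()}",
            f"chains: {self.samples.n_chains}  draws/chain: "
            f"{self.samples.n_draws}",
            "",
            frame.to_string(index=False,
                            float_format=lambda v: f"{v: .3f}"),
            "",
            "Regional seasonal site use Z[t] (median [95% CI]):",
        ]
        for t, year in enumerate(h.years):
            lines.append(f"  {year}: {su.Z_median[t]:.3f} "
                         f"[{su.Z_lo[t]:.3f}, {su.Z_hi[t]:.3f}]")
        return "\n".join(lines)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.samples.save(directory / "samples")
        self.summary_frame().to_csv(directory / "parameter_summary.csv",
                                    index=False)
        self.site_use().to_frame(self.history).to_csv(
            directory / "site_use.csv", index=False)
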