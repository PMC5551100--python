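"""Probability functions of the seasonal site-use model.

The model is a two-level hidden Markov chain per site and season.  The
latent daily occupancy state u[d] evolves by

    psi[d] = u[d-1] * phi[d-1] + (1 - u[d-1]) * gamma[d-1],
    u[d] ~ Bernoulli(psi[d]),

with day-varying persistence phi and colonization gamma given by probit
regressions on a (standardized) quadratic of the day-of-season, plus site
and year random effects.  Each visit j on day d yields an observation

    y[j,d] ~ Bernoulli(u[d] * p[j,d]),

where the per-visit detection probability saturates with the visit's
species list length: p = SLL / (SLL + delta), and log(delta) is a linear
function of a site intercept and the annual long-list proportion PLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, log_ndtr

from .ingest import MISSING, DetectionHistory

__all__ = [
    "ModelParams", "DayCovariate", "detection_prob", "delta_from_covariates",
    "seasonal_rate", "occupancy_recursion", "day_obs_likelihood",
    "marginal_loglik", "total_loglik", "standardized_jday", "rate_curves",
]


def standardized_jday(n_days: int) -> "DayCovariate":
    """Day-of-season covariate, centred and scaled to mean 0, SD 1.

    The raw quadratic in day number is numerically hostile under a probit
    link with vague priors; the standardized version is equivalent up to a
    reparameterization of the coefficients.
    """
    raw = np.arange(1, n_days + 1, dtype=float)
    scale = raw.std() if n_days > 1 else 1.0
    return DayCovariate(values=(raw - raw.mean()) / scale)


@dataclass(frozen=True)
class DayCovariate:
    """Standardized day-of-season values, one per day."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ModelParams:
    """All process and detection parameters of the seasonal model.

    Shapes: coefficient triples ``(c1, c2, c3)`` for the persistence and
    colonization probit quadratics; per-site and per-year random effects;
    random-effect SDs (sigma = tau**-0.5); per-site log-delta intercepts
    ``dcoef1`` with a common PLL slope ``dcoef2``; and an explicit
    initial-day occupancy probability ``psi1[t, i]`` (the day-to-day
    recursion needs a start state, which the seasonal structure itself does
    not supply).
    """

    pcoef: np.ndarray                 # (3,) persistence probit quadratic
    gcoef: np.ndarray                 # (3,) colonization probit quadratic
    eps_p_site: np.ndarray            # (I,)
    eps_g_site: np.ndarray            # (I,)
    eps_p_year: np.ndarray            # (T,)
    eps_g_year: np.ndarray            # (T,)
    dcoef1: np.ndarray                # (I,) log-delta site intercepts
    dcoef2: float                     # PLL slope on log delta
    psi1: np.ndarray                  # (T, I) day-1 occupancy probability
    sigma_p_site: float = 1.0
    sigma_g_site: float = 1.0
    sigma_p_year: float = 1.0
    sigma_g_year: float = 1.0

    def __post_init__(self):
        for name in ("pcoef", "gcoef", "eps_p_site", "eps_g_site",
                     "eps_p_year", "eps_g_year", "dcoef1", "psi1"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if not np.isfinite(self.pcoef).all() or not np.isfinite(self.gcoef).all():
            raise ValueError("non-finite regression coefficients")
        if ((self.psi1 < 0) | (self.psi1 > 1)).any():
            raise ValueError("psi1 outside [0, 1]")
        for s in (self.sigma_p_site, self.sigma_g_site,
                  self.sigma_p_year, self.sigma_g_year):
            if s <= 0:
                raise ValueError("random-effect SDs must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.dcoef1)

    @property
    def n_years(self) -> int:
        return self.psi1.shape[0]


def detection_prob(sll, delta):
    """Per-visit detection probability p = SLL / (SLL + delta).

    ``delta`` is the list length at which detection reaches 0.5; p increases
    with SLL and approaches (never reaches) 1.  ``delta = 0`` is allowed as
    the perfect-detection limit.
    """
    sll = np.asarray(sll, float)
    delta = np.asarray(delta, float)
    if (sll < 0).any() or (delta < 0).any():
        raise ValueError("sll and delta must be non-negative")
    with np.errstate(invalid="ignore"):
        p = np.where((sll == 0) & (delta == 0), 0.0, sll / (sll + delta))
    return p if p.ndim else float(p)


def delta_from_covariates(dcoef1_i, dcoef2, pll_t, dcoef3=0.0, window=0.0):
    """Half-saturation list length: delta = exp(dcoef1_i + dcoef2 * PLL_t).

    ``dcoef3``/``window`` form an optional within-season time-window hook
    (e.g. a month indicator) on the log scale; both default to 0 and the
    sampler does not estimate them — fitting day-level detection trends
    interferes with the occupancy submodel.
    """
    out = np.exp(np.asarray(dcoef1_i, float) + np.asarray(dcoef2, float)
                 * np.asarray(pll_t, float)
                 + np.asarray(dcoef3, float) * np.asarray(window, float))
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite detection coefficients")
    return out if np.ndim(out) else float(out)


def seasonal_rate(coefs, jday, eps_site=0.0, eps_year=0.0):
    """Probit-linked daily rate Phi(c1 + c2*jday + c3*jday^2 + eps_i + eps_t).

    Used for both persistence (phi) and colonization (gamma).
    """
    c1, c2, c3 = (float(c) for c in coefs)
    lin = c1 + c2 * np.asarray(jday, float) + c3 * np.asarray(jday, float) ** 2 \
        + np.asarray(eps_site, float) + np.asarray(eps_year, float)
    if not np.all(np.isfinite(lin)):
        raise ValueError("non-finite linear predictor")
    out = ndtr(lin)
    return out if np.ndim(out) else float(out)


def occupancy_recursion(u_prev, phi, gamma):
    """Next-day occupancy probability psi = u*phi + (1-u)*gamma."""
    u = np.asarray(u_prev)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("u_prev must be binary")
    out = u * np.asarray(phi, float) + (1 - u) * np.asarray(gamma, float)
    return out if np.ndim(out) else float(out)


def day_obs_likelihood(y_vec, p_vec, u) -> float:
    """Likelihood of one day's visits given the occupancy state.

    Product over non-missing visits of Bernoulli(u * p); missing visits
    contribute a factor of 1.  A detection under absence gives exactly 0.
    """
    if u not in (0, 1):
        raise ValueError("u must be 0 or 1")
    y = np.asarray(y_vec, float)
    p = np.asarray(p_vec, float)
    keep = ~np.isnan(y) & (y != MISSING)
    y, p = y[keep], p[keep]
    up = u * p
    return float(np.prod(np.where(y == 1, up, 1.0 - up)))


def rate_curves(params: ModelParams, jday: DayCovariate):
    """Persistence and colonization arrays phi[d, t, i], gamma[d, t, i].

    Element d is the rate governing the transition from day d+1 to day d+2
    (1-based), i.e. it is evaluated at jday[d] for d = 0..n-2.
    """
    x = jday.values[:-1]
    T, I = params.n_years, params.n_sites
    lin_p = (params.pcoef[0] + params.pcoef[1] * x + params.pcoef[2] * x ** 2)
    lin_g = (params.gcoef[0] + params.gcoef[1] * x + params.gcoef[2] * x ** 2)
    phi = ndtr(lin_p[:, None, None] + params.eps_p_year[None, :, None]
               + params.eps_p_site[None, None, :])
    gamma = ndtr(lin_g[:, None, None] + params.eps_g_year[None, :, None]
                 + params.eps_g_site[None, None, :])
    assert phi.shape == (len(x), T, I)
    return phi, gamma


def _day_logliks(y_td, sll_td, delta):
    """Per-day observation log-likelihoods (log B) for both latent states.

    ``y_td``/``sll_td`` are (J, D) slices for one site-year.  Returns
    ``(logb0, logb1)`` of shape (D,); a day with no visits contributes 0.
    """
    J, D = y_td.shape
    p = np.zeros((J, D))
    obs = y_td != MISSING
    p[obs] = detection_prob(sll_td[obs], delta)
    logb0 = np.where((y_td == 1).any(axis=0), -np.inf, 0.0)
    with np.errstate(divide="ignore"):
        terms = np.where(y_td == 1, np.log(p), np.log1p(-p))
    terms[~obs] = 0.0
    logb1 = terms.sum(axis=0)
    return logb0, logb1


def marginal_loglik(history: DetectionHistory, params: ModelParams,
                    year_index: int, site_index: int,
                    jday: DayCovariate | None = None) -> float:
    """Marginal log-likelihood of one site-year, latent states summed out.

    Forward algorithm over the 2-state daily chain; a fully missing
    site-year has log-likelihood 0.
    """
    t, i = year_index, site_index
    if jday is None:
        jday = standardized_jday(history.n_days)
    delta = delta_from_covariates(params.dcoef1[i], params.dcoef2,
                                  history.pll[t])
    logb0, logb1 = _day_logliks(history.y[:, :, t, i],
                                history.sll[:, :, t, i], delta)
    phi, gamma = rate_curves(params, jday)
    return _forward_loglik(logb0, logb1, phi[:, t, i], gamma[:, t, i],
                           float(params.psi1[t, i]))


def _forward_loglik(logb0, logb1, phi, gamma, psi1) -> float:
    D = len(logb0)
    with np.errstate(divide="ignore"):
        a0 = np.log1p(-psi1) + logb0[0]
        a1 = np.log(psi1) + logb1[0]
    total = 0.0
    for d in range(1, D):
        ph, ga = phi[d - 1], gamma[d - 1]
        with np.errstate(divide="ignore"):
            n0 = np.logaddexp(a0 + np.log(max(1 - ga, 1e-300)),
                              a1 + np.log(max(1 - ph, 1e-300))) + logb0[d]
            n1 = np.logaddexp(a0 + np.log(max(ga, 1e-300)),
                              a1 + np.log(max(ph, 1e-300))) + logb1[d]
        m = max(n0, n1)
        if not np.isfinite(m):
            return -np.inf
        a0, a1 = n0 - m, n1 - m
        total += m
    return float(total + np.logaddexp(a0, a1))


def total_loglik(history: DetectionHistory, params: ModelParams,
                 jday: DayCovariate | None = None) -> float:
    """Joint marginal log-likelihood; factorizes over sites and years."""
    if jday is None:
        jday = standardized_jday(history.n_days)
    return float(sum(
        marginal_loglik(history, params, t, i, jday)
        for t in range(history.n_years) for i in range(history.n_sites)))
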