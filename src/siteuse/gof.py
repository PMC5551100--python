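"""Posterior predictive goodness-of-fit checks.

For each retained posterior draw, observations are replicated under the
fitted model with the *observed* effort pattern (visit slots, list lengths
and missingness taken verbatim from the data).  Observed and replicated
mean annual site use are compared with the model's expectation via sums of
squares of Pearson-style residuals, one per site, yielding site-specific
Bayesian p-values: the fraction of draws in which the replicated-data
discrepancy exceeds the observed-data discrepancy.  Values near 0.5 mean
the model reproduces its own data; values near 0 or 1 flag under-/overfit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import MISSING, DetectionHistory
from .derived import observed_site_use

__all__ = ["GofReport", "replicate_observations", "expected_site_use",
           "ssq_discrepancy", "bayes_p_value", "gof_report"]

_DENOM_FLOOR = 1e-12


def _p_arrays(history: DetectionHistory, dcoef1, dcoef2):
    """Per-visit detection probabilities (J, D, T, I); NaN where missing."""
    delta = np.exp(np.asarray(dcoef1)[None, :] + dcoef2
                   * np.asarray(history.pll)[:, None])       # (T, I)
    with np.errstate(invalid="ignore"):
        p = history.sll / (history.sll + delta[None, None, :, :])
    return p


def replicate_observations(u: np.ndarray, p: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Replicate a detection array: y_new ~ Bernoulli(u * p) per real visit.

    ``u`` is one latent draw (D, T, I); ``p`` the matching per-visit
    detection probabilities with NaN at missing slots.  The output carries
    the same missingness pattern.
    """
    obs = ~np.isnan(p)
    up = np.where(obs, u[None, ...] * np.nan_to_num(p), 0.0)
    y_new = np.where(obs, (rng.random(p.shape) < up).astype(np.int8),
                     np.int8(MISSING))
    return y_new.astype(np.int8)


def expected_site_use(u: np.ndarray, p: np.ndarray, n_days: int):
    """Model-expected observed site use and mean daily detectability.

    w̄[t, i] = Σ_d u[d] * (1 − Π_j (1 − p_j)) / n — the average probability
    of detecting the species at least once per day, given presence.  Also
    returns p̄[t, i], the mean over all n days of the at-least-one-detection
    probability (zero on unvisited days), used in the discrepancy
    denominator.
    """
    one_minus = np.where(np.isnan(p), 1.0, 1.0 - p)
    day_det = 1.0 - one_minus.prod(axis=0)          # (D, T, I)
    wbar = (u * day_det).sum(axis=0) / n_days
    pbar = day_det.sum(axis=0) / n_days
    return wbar, pbar


def ssq_discrepancy(w_vec, wbar_vec, pbar_vec, reading: str = "pearson"):
    """Per-site sum over years of squared site-use discrepancies.

    ``reading="pearson"`` (default): Σ_t (w − w̄)² / (w̄ (1 − p̄)) — the
    squared residual over a binomial-style variance proxy.
    ``reading="literal"``: Σ_t ((w − w̄) / (w̄ (1 − p̄)))² — the square
    applied to the whole ratio, as the discrepancy formula can also be
    typeset.  Denominators are floored at 1e-12; the caller is expected to
    flag sites whose expectation is zero in every year.
    """
    w = np.asarray(w_vec, float)
    wbar = np.asarray(wbar_vec, float)
    pbar = np.asarray(pbar_vec, float)
    denom = np.maximum(wbar * (1.0 - pbar), _DENOM_FLOOR)
    if reading == "pearson":
        terms = (w - wbar) ** 2 / denom
    elif reading == "literal":
        terms = ((w - wbar) / denom) ** 2
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return terms.sum(axis=-1)


def bayes_p_value(ssq_obs_draws, ssq_new_draws):
    """Fraction of paired draws with replicated discrepancy above observed."""
    obs = np.asarray(ssq_obs_draws, float)
    new = np.asarray(ssq_new_draws, float)
    if obs.shape != new.shape:
        raise ValueError("paired draw arrays must have equal shape")
    return (new > obs).mean(axis=0)


@dataclass
class GofReport:
    """Observed/replicated site-use statistics and Bayesian p-values."""

    w_obs: np.ndarray            # (T, I) observed site use
    w_new: np.ndarray            # (R, T, I) replicated site use per draw
    w_bar: np.ndarray            # (R, T, I) expected site use per draw
    ssq_obs: np.ndarray          # (R, I)
    ssq_new: np.ndarray          # (R, I)
    bayes_p: np.ndarray          # (I,) NaN where no information
    no_information: np.ndarray   # (I,) bool: expectation ~0 in all years
    reading: str = "pearson"
    sites: list = field(default_factory=list)
    years: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        sites = self.sites or list(range(len(self.bayes_p)))
        return pd.DataFrame({
            "site": sites,
            "bayes_p": self.bayes_p,
            "ssq_obs_median": np.median(self.ssq_obs, axis=0),
            "ssq_new_median": np.median(self.ssq_new, axis=0),
            "no_information": self.no_information,
        })

    def discrepancy_points(self) -> pd.DataFrame:
        """Paired (observed, replicated) annual site use for the 1:1 plot."""
        R, T, I = self.w_new.shape
        obs = np.broadcast_to(self.w_obs, (R, T, I)).ravel()
        return pd.DataFrame({"observed": obs, "replicated": self.w_new.ravel()})

    def plot_discrepancy(self, ax=None):
        """Scatter of observed vs. replicated site use with the 1:1 line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pts = self.discrepancy_points()
        ax.plot(pts["observed"], pts["replicated"], ".", alpha=0.15, ms=3)
        lim = max(pts.max().max(), 0.05)
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("observed mean annual site use")
        ax.set_ylabel("replicated mean annual site use")
        return ax

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "gof_sites.csv", index=False)
        self.discrepancy_points().to_csv(directory / "gof_points.csv",
                                         index=False)


def gof_report(results, seed: int = 0, n_rep: int | None = 400,
               reading: str = "pearson") -> GofReport:
    """Full posterior predictive check for a fitted seasonal model.

    ``n_rep`` caps the number of posterior draws replicated (evenly
    subsampled); ``None`` uses every draw.
    """
    history = results.history
    samples = results.samples
    rng = np.random.default_rng(seed)

    u_all = samples.flat_u()
    d1_all = samples.flat("dcoef1")
    d2_all = samples.flat("dcoef2")
    n_total = u_all.shape[0]
    if n_rep is None or n_rep >= n_total:
        keep = np.arange(n_total)
    else:
        keep = np.linspace(0, n_total - 1, n_rep).astype(int)

    w_obs = observed_site_use(history)
    T, I = w_obs.shape
    R = len(keep)
    w_new = np.empty((R, T, I))
    w_bar = np.empty((R, T, I))
    ssq_obs = np.empty((R, I))
    ssq_new = np.empty((R, I))
    n = history.n_days
    for r, idx in enumerate(keep):
        u = u_all[idx].astype(float)
        p = _p_arrays(history, d1_all[idx], float(d2_all[idx]))
        wbar, pbar = expected_site_use(u, p, n)
        y_new = replicate_observations(u, p, rng)
        wnew = (y_new == 1).any(axis=0).sum(axis=0) / n
        w_bar[r], w_new[r] = wbar, wnew
        ssq_obs[r] = ssq_discrepancy(w_obs.T, wbar.T, pbar.T, reading)
        ssq_new[r] = ssq_discrepancy(wnew.T, wbar.T, pbar.T, reading)

    no_info = (w_bar.max(axis=(0, 1)) < 1e-8)
    p_vals = bayes_p_value(ssq_obs, ssq_new)
    p_vals = np.where(no_info, np.nan, p_vals)
    return GofReport(
        w_obs=w_obs, w_new=w_new, w_bar=w_bar, ssq_obs=ssq_obs,
        ssq_new=ssq_new, bayes_p=p_vals, no_information=no_info,
        reading=reading, sites=list(history.sites), years=list(history.years),
    )
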