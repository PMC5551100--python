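"""Derived site-use quantities.

Seasonal site use summarizes the latent daily occupancy states: per draw,
z[t, i] is the fraction of season days the site was occupied and Z[t] its
average over sites ("regional" site use).  Observed site use w[t, i] is the
analogous data-level statistic, built from the daily maximum detection
status; unvisited days count as zeros because the denominator is the full
season length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import DetectionHistory

__all__ = ["SiteUseSummary", "site_use", "observed_site_use"]


@dataclass
class SiteUseSummary:
    """Posterior draws and summaries of seasonal site use."""

    z_draws: np.ndarray       # (n_draws, T, I)
    Z_draws: np.ndarray       # (n_draws, T)
    z_median: np.ndarray      # (T, I)
    z_lo: np.ndarray
    z_hi: np.ndarray
    Z_median: np.ndarray      # (T,)
    Z_lo: np.ndarray
    Z_hi: np.ndarray
    n_days: int

    def to_frame(self, history: DetectionHistory | None = None) -> pd.DataFrame:
        """Tidy (site, year, statistic, value) table of the summaries."""
        T, I = self.z_median.shape
        years = history.years if history is not None else list(range(T))
        sites = history.sites if history is not None else list(range(I))
        rows = []
        for t in range(T):
            for i in range(I):
                for stat, arr in (("median", self.z_median),
                                  ("ci2.5", self.z_lo), ("ci97.5", self.z_hi)):
                    rows.append((sites[i], years[t], f"z_{stat}", arr[t, i]))
            for stat, arr in (("median", self.Z_median),
                              ("ci2.5", self.Z_lo), ("ci97.5", self.Z_hi)):
                rows.append(("<region>", years[t], f"Z_{stat}", arr[t]))
        return pd.DataFrame(rows, columns=["site", "year", "statistic", "value"])


def site_use(u_draws: np.ndarray) -> SiteUseSummary:
    """Summarize site use from latent occupancy draws.

    ``u_draws`` has shape (n_draws, days, years, sites) with binary entries.
    Summaries are the posterior median and central 95% interval.
    """
    u = np.asarray(u_draws)
    if u.ndim != 4:
        raise ValueError("u_draws must be (draw, day, year, site)")
    z = u.mean(axis=1, dtype=float)            # (n, T, I)
    Z = z.mean(axis=2)                         # (n, T)
    lo, hi = 2.5, 97.5
    return SiteUseSummary(
        z_draws=z, Z_draws=Z,
        z_median=np.median(z, axis=0),
        z_lo=np.percentile(z, lo, axis=0), z_hi=np.percentile(z, hi, axis=0),
        Z_median=np.median(Z, axis=0),
        Z_lo=np.percentile(Z, lo, axis=0), Z_hi=np.percentile(Z, hi, axis=0),
        n_days=u.shape[1],
    )


def observed_site_use(history: DetectionHistory) -> np.ndarray:
    """Observed mean annual site use w[t, i].

    The daily detection status is the maximum over the day's visits; days
    without visits contribute 0, and the average is over the full season
    (n days), matching the denominator used for the latent statistic.
    """
    detected = (history.y == 1).any(axis=0)    # (D, T, I)
    return detected.sum(axis=0) / history.n_days
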