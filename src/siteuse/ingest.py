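"""Turn raw opportunistic species records into replicated detection histories.

Opportunistic databases store one row per *report* (species, site, date,
observer) with no information about species that were looked for but not
seen.  Nondetections are reconstructed from the reports themselves: every
unique observer reporting at least one study species at a site on a day
constitutes a replicate *visit*, and a visit that does not mention the focal
species is a nondetection of it.  The number of distinct study species on a
visit (the species list length, SLL) is kept as a per-visit effort proxy,
and the annual proportion of long lists (PLL) as a reporting-behaviour
covariate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd

#: Sentinel for "no visit in this replicate slot" in integer detection arrays.
MISSING: int = -1

REQUIRED_COLUMNS = ("species", "site", "date", "observer")


class NoUsableRecordsError(ValueError):
    """Raised when no records remain after filtering to the season window
    and study species list."""


class MalformedRecordError(ValueError):
    """Raised when a record row cannot be parsed; carries the row label."""

    def __init__(self, row_id, message: str):
        self.row_id = row_id
        super().__init__(f"record row {row_id!r}: {message}")


@dataclass(frozen=True)
class SeasonWindow:
    """A within-year study season.

    Day 1 is the season start (month/day of each calendar year); the season
    spans ``n_days`` consecutive days.  Records dated after day ``n_days``
    but within ``grace_days`` of the window end are treated as trailing data
    (dropped with a warning) rather than silently out of season — a
    three-month window such as April 1 – June 30 spans 91 calendar days
    while the season is conventionally treated as 90.
    """

    start_month: int = 4
    start_day: int = 1
    n_days: int = 90
    grace_days: int = 7

    def start(self, year: int) -> _date:
        return _date(year, self.start_month, self.start_day)

    def day_index(self, d: _date) -> int:
        """1-based day-of-season index (may fall outside [1, n_days])."""
        return (d - self.start(d.year)).days + 1


def read_records(path) -> pd.DataFrame:
    """Read a delimited record table (CSV or TSV, sniffed from the header)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table lacks required columns: {missing}")
    return df


def _parse_dates(records: pd.DataFrame) -> pd.Series:
    out = []
    for row_id, value in records["date"].items():
        if isinstance(value, _date):
            out.append(value)
            continue
        try:
            out.append(_date.fromisoformat(str(value)))
        except ValueError as exc:
            raise MalformedRecordError(row_id, f"unparseable date {value!r}") from exc
    return pd.Series(out, index=records.index)


def build_visits(records: pd.DataFrame, season: SeasonWindow,
                 study_species) -> pd.DataFrame:
    """Group records into replicate visits.

    One visit per unique (observer, site, date).  The visit's species set is
    restricted to the study list before computing SLL, so SLL counts study
    species only.

    Returns a data frame with columns
    ``site, year, day, observer, species_set, sll`` (one row per visit).
    """
    study = set(study_species)
    if not study:
        raise ValueError("study species list is empty")
    for col in REQUIRED_COLUMNS:
        if records[col].isna().any():
            bad = records.index[records[col].isna()][0]
            raise MalformedRecordError(bad, f"null value in column {col!r}")

    rec = records.copy()
    rec["date"] = _parse_dates(rec)
    rec = rec[rec["species"].isin(study)]
    day = rec["date"].map(season.day_index)
    trailing = (day > season.n_days) & (day <= season.n_days + season.grace_days)
    if trailing.any():
        warnings.warn(
            f"{int(trailing.sum())} record(s) fall on season days "
            f"{season.n_days + 1}..{season.n_days + season.grace_days} "
            f"(beyond the {season.n_days}-day season) and were dropped",
            stacklevel=2,
        )
    rec = rec[(day >= 1) & (day <= season.n_days)]
    if rec.empty:
        raise NoUsableRecordsError(
            "no usable records after filtering to the season window "
            "and study species list"
        )

    rec["year"] = rec["date"].map(lambda d: d.year)
    rec["day"] = rec["date"].map(season.day_index)
    grouped = (
        rec.groupby(["site", "year", "day", "observer"], sort=True)["species"]
        .agg(lambda s: frozenset(s))
        .reset_index()
        .rename(columns={"species": "species_set"})
    )
    grouped["sll"] = grouped["species_set"].map(len)
    return grouped[["site", "year", "day", "observer", "species_set", "sll"]]


def cap_visits(visits: pd.DataFrame, max_visits: int = 40) -> pd.DataFrame:
    """Retain at most ``max_visits`` visits per (site, year, day), keeping
    those with the longest species lists.

    Ties at the cap boundary are broken by observer id (ascending), which
    makes the filter deterministic.
    """
    if max_visits < 1:
        raise ValueError("max_visits must be >= 1")
    ordered = visits.sort_values(
        ["site", "year", "day", "sll", "observer"],
        ascending=[True, True, True, False, True],
        kind="stable",
    )
    capped = ordered.groupby(["site", "year", "day"], sort=False).head(max_visits)
    return capped.reset_index(drop=True)


def compute_pll(visits: pd.DataFrame, long_threshold: int = 10) -> pd.Series:
    """Annual proportion of long species lists, pooled over all sites.

    PLL[t] = (# visits in year t with SLL >= long_threshold) / (# visits in
    year t).  Every year present must have at least one visit (it does by
    construction here, but an externally supplied year grid may not).
    """
    if long_threshold < 1:
        raise ValueError("long_threshold must be >= 1")
    totals = visits.groupby("year").size()
    longs = visits[visits["sll"] >= long_threshold].groupby("year").size()
    pll = longs.reindex(totals.index, fill_value=0) / totals
    pll.name = "pll"
    return pll


@dataclass
class DetectionHistory:
    """Replicated daily detection/nondetection data for one focal species.

    ``y[j, d, t, i]`` is 1 for a detection on visit ``j``, 0 for a
    nondetection and :data:`MISSING` (−1) where no visit occupies the slot;
    ``sll`` carries the matching per-visit list lengths (NaN where missing).
    Days and sites without any visit are entirely missing.  ``pll[t]`` is the
    long-list proportion covariate per year.
    """

    y: np.ndarray            # int8, shape (J, D, T, I)
    sll: np.ndarray          # float64, same shape, NaN where y is MISSING
    nvisits: np.ndarray      # int32, shape (D, T, I)
    pll: np.ndarray          # float64, shape (T,)
    focal_species: str
    sites: list = field(default_factory=list)
    years: list = field(default_factory=list)
    season: SeasonWindow = field(default_factory=SeasonWindow)
    max_visits: int | None = None
    long_threshold: int = 10

    @property
    def n_days(self) -> int:
        return self.y.shape[1]

    @property
    def n_years(self) -> int:
        return self.y.shape[2]

    @property
    def n_sites(self) -> int:
        return self.y.shape[3]

    @property
    def max_slots(self) -> int:
        return self.y.shape[0]

    def n_detections(self) -> int:
        return int((self.y == 1).sum())

    def validate(self) -> None:
        if self.y.shape != self.sll.shape:
            raise ValueError("y and sll shapes differ")
        if ((self.y == MISSING) != np.isnan(self.sll)).any():
            raise ValueError("missingness of y and sll disagree")
        if (self.nvisits != (self.y != MISSING).sum(axis=0)).any():
            raise ValueError("nvisits inconsistent with y")
        if not ((self.pll >= 0) & (self.pll <= 1)).all():
            raise ValueError("pll outside [0, 1]")

    # -- serialization: long-format CSV + JSON sidecar --------------------

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        j, d, t, i = np.nonzero(self.y != MISSING)
        pd.DataFrame({
            "slot": j, "day": d + 1,
            "year": np.asarray(self.years)[t],
            "site": np.asarray(self.sites)[i],
            "y": self.y[j, d, t, i],
            "sll": self.sll[j, d, t, i].astype(int),
        }).to_csv(directory / "detections.csv", index=False)
        pd.DataFrame({"year": self.years, "pll": self.pll}).to_csv(
            directory / "pll.csv", index=False)
        meta = {
            "focal_species": self.focal_species,
            "sites": list(map(str, self.sites)),
            "years": [int(y) for y in self.years],
            "dims": {"max_slots": self.max_slots, "n_days": self.n_days,
                     "n_years": self.n_years, "n_sites": self.n_sites},
            "season": {"start_month": self.season.start_month,
                       "start_day": self.season.start_day,
                       "n_days": self.season.n_days},
            "max_visits": self.max_visits,
            "long_threshold": self.long_threshold,
        }
        (directory / "history.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "DetectionHistory":
        from pathlib import Path

        directory = Path(directory)
        meta = json.loads((directory / "history.json").read_text())
        dims = meta["dims"]
        shape = (dims["max_slots"], dims["n_days"], dims["n_years"],
                 dims["n_sites"])
        y = np.full(shape, MISSING, dtype=np.int8)
        sll = np.full(shape, np.nan)
        site_ix = {s: k for k, s in enumerate(meta["sites"])}
        year_ix = {y_: k for k, y_ in enumerate(meta["years"])}
        det = pd.read_csv(directory / "detections.csv")
        for row in det.itertuples(index=False):
            t, i = year_ix[int(row.year)], site_ix[str(row.site)]
            y[row.slot, row.day - 1, t, i] = row.y
            sll[row.slot, row.day - 1, t, i] = row.sll
        pll = pd.read_csv(directory / "pll.csv").set_index("year")["pll"]
        season = SeasonWindow(**{k: meta["season"][k]
                                 for k in ("start_month", "start_day", "n_days")})
        hist = cls(
            y=y, sll=sll, nvisits=(y != MISSING).sum(axis=0).astype(np.int32),
            pll=pll.reindex(meta["years"]).to_numpy(float),
            focal_species=meta["focal_species"], sites=meta["sites"],
            years=meta["years"], season=season,
            max_visits=meta["max_visits"], long_threshold=meta["long_threshold"],
        )
        hist.validate()
        return hist


def build_detection_history(visits: pd.DataFrame, focal_species: str,
                            study_species, season: SeasonWindow,
                            long_threshold: int = 10,
                            max_visits: int | None = None,
                            sites=None, years=None) -> DetectionHistory:
    """Assemble the 4-way detection array for one focal species.

    Visit slots within a (site, year, day) cell are ordered by descending
    SLL then observer id — the same ordering :func:`cap_visits` uses — so
    slot 0 always holds the longest list.  ``sites``/``years`` may be given
    to fix the grid (e.g. when looping over many focal species); otherwise
    they are taken from the visit table.
    """
    if focal_species not in set(study_species):
        raise ValueError(f"focal species {focal_species!r} not in study list")
    sites = sorted(visits["site"].unique()) if sites is None else list(sites)
    years = sorted(visits["year"].unique()) if years is None else list(years)
    site_ix = {s: k for k, s in enumerate(sites)}
    year_ix = {y: k for k, y in enumerate(years)}
    n_days = season.n_days

    ordered = visits.sort_values(
        ["site", "year", "day", "sll", "observer"],
        ascending=[True, True, True, False, True], kind="stable")
    slot = ordered.groupby(["site", "year", "day"], sort=False).cumcount()
    max_slots = int(slot.max()) + 1 if len(slot) else 1
    if max_visits is not None:
        max_slots = min(max_slots, max_visits)

    shape = (max_slots, n_days, len(years), len(sites))
    y = np.full(shape, MISSING, dtype=np.int8)
    sll = np.full(shape, np.nan)
    for (row, j) in zip(ordered.itertuples(index=False), slot):
        if j >= max_slots:
            continue
        t, i = year_ix[row.year], site_ix[row.site]
        y[j, row.day - 1, t, i] = 1 if focal_species in row.species_set else 0
        sll[j, row.day - 1, t, i] = row.sll

    pll = compute_pll(visits, long_threshold=long_threshold)
    missing_years = [yr for yr in years if yr not in pll.index]
    if missing_years:
        raise ValueError(
            f"PLL covariate undefined: no visits in year(s) {missing_years}")
    hist = DetectionHistory(
        y=y, sll=sll, nvisits=(y != MISSING).sum(axis=0).astype(np.int32),
        pll=pll.reindex(years).to_numpy(float),
        focal_species=focal_species, sites=sites, years=years, season=season,
        max_visits=max_visits, long_threshold=long_threshold,
    )
    hist.validate()
    return hist
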