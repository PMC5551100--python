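"""Record-to-detection-history construction and its filters."""

import numpy as np
import pandas as pd
import pytest

from siteuse import (MISSING, MalformedRecordError, NoUsableRecordsError,
                     SeasonWindow, build_detection_history, build_visits,
                     cap_visits, compute_pll, DetectionHistory)
from siteuse.ingest import read_records

SEASON = SeasonWindow(start_month=4, start_day=1, n_days=90)
STUDY = [f"sp{k}" for k in range(1, 6)]


class TestBuildVisits:
    def test_same_observer_same_day_is_one_visit(self):
        rec = pd.DataFrame({
            "species": ["sp1", "sp2"], "site": ["A", "A"],
            "date": ["2010-04-10", "2010-04-10"], "observer": ["o", "o"],
        })
        v = build_visits(rec, SEASON, STUDY)
        assert len(v) == 1
        assert v["sll"].iloc[0] == 2
        assert v["day"].iloc[0] == 10

    def test_single_row_single_visit(self):
        rec = pd.DataFrame({"species": ["sp1"], "site": ["A"],
                            "date": ["2010-04-01"], "observer": ["o"]})
        v = build_visits(rec, SEASON, STUDY)
        assert len(v) == 1 and v["sll"].iloc[0] == 1 and v["day"].iloc[0] == 1

    def test_two_observers_brute_force_counts(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        # independent group-and-count over the toy table
        expected = {}
        for _, row in toy_records.iterrows():
            key = (row["observer"], row["site"], row["date"])
            expected.setdefault(key, set()).add(row["species"])
        assert len(v) == len(expected)
        for (obs, site, date), spset in expected.items():
            day = SEASON.day_index(pd.Timestamp(date).date())
            match = v[(v["observer"] == obs) & (v["site"] == site)
                      & (v["day"] == day)]
            assert len(match) == 1
            assert match["sll"].iloc[0] == len(spset)
            assert match["species_set"].iloc[0] == frozenset(spset)

    def test_species_set_restricted_to_study_list(self):
        rec = pd.DataFrame({
            "species": ["sp1", "unlisted"], "site": ["A", "A"],
            "date": ["2010-04-10"] * 2, "observer": ["o", "o"]})
        v = build_visits(rec, SEASON, STUDY)
        assert v["sll"].iloc[0] == 1

    def test_empty_after_filter_raises(self):
        rec = pd.DataFrame({"species": ["nope"], "site": ["A"],
                            "date": ["2010-04-10"], "observer": ["o"]})
        with pytest.raises(NoUsableRecordsError):
            build_visits(rec, SEASON, STUDY)

    def test_malformed_date_names_the_row(self):
        rec = pd.DataFrame({"species": ["sp1", "sp1"], "site": ["A", "A"],
                            "date": ["2010-04-10", "not-a-date"],
                            "observer": ["o", "o"]})
        with pytest.raises(MalformedRecordError, match="1"):
            build_visits(rec, SEASON, STUDY)

    def test_null_field_rejected(self):
        rec = pd.DataFrame({"species": ["sp1"], "site": [None],
                            "date": ["2010-04-10"], "observer": ["o"]})
        with pytest.raises(MalformedRecordError):
            build_visits(rec, SEASON, STUDY)

    def test_trailing_day_dropped_with_warning(self):
        # April 1 + 89 days = June 29 is day 90; June 30 is a trailing day
        rec = pd.DataFrame({
            "species": ["sp1", "sp2"], "site": ["A", "A"],
            "date": ["2010-06-29", "2010-06-30"], "observer": ["o", "o"]})
        with pytest.warns(UserWarning, match="beyond the 90-day season"):
            v = build_visits(rec, SEASON, STUDY)
        assert v["day"].max() == 90 and len(v) == 1


class TestCapVisits:
    @staticmethod
    def _one_day_visits(slls, observers=None):
        n = len(slls)
        observers = observers or [f"o{k:03d}" for k in range(n)]
        return pd.DataFrame({
            "site": ["A"] * n, "year": [2010] * n, "day": [7] * n,
            "observer": observers,
            "species_set": [frozenset(f"x{j}" for j in range(s)) for s in slls],
            "sll": slls,
        })

    def test_keeps_longest_lists(self):
        v = self._one_day_visits(list(range(1, 46)))
        capped = cap_visits(v, 40)
        assert len(capped) == 40
        assert sorted(capped["sll"]) == list(range(6, 46))

    def test_below_cap_unchanged(self):
        v = self._one_day_visits([3, 1, 2])
        out = cap_visits(v, 40)
        assert sorted(out["sll"]) == [1, 2, 3]

    def test_tie_broken_by_observer_id(self):
        v = self._one_day_visits([1] * 41)
        out = cap_visits(v, 40)
        assert len(out) == 40
        # deterministic: the alphabetically last observer is dropped
        assert "o040" not in set(out["observer"])

    def test_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            cap_visits(self._one_day_visits([1]), 0)


class TestComputePll:
    def test_printed_style_toy(self):
        v = pd.DataFrame({"year": [2010] * 4, "sll": [1, 2, 10, 12],
                          "site": ["A", "B", "A", "B"]})
        assert compute_pll(v, 10).loc[2010] == 0.5

    @pytest.mark.parametrize("slls,expected", [([1, 2, 3], 0.0),
                                               ([10, 20, 45], 1.0)])
    def test_extremes(self, slls, expected):
        v = pd.DataFrame({"year": [2010] * len(slls), "sll": slls,
                          "site": ["A"] * len(slls)})
        assert compute_pll(v, 10).loc[2010] == expected

    def test_site_permutation_invariance(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        swapped = v.assign(site=v["site"].map({"siteA": "siteB",
                                               "siteB": "siteA"}))
        pd.testing.assert_series_equal(compute_pll(v, 2), compute_pll(swapped, 2))


class TestDetectionHistory:
    def test_focal_membership_defines_detection(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        h = build_detection_history(v, "sp1", STUDY, SEASON, long_threshold=2)
        # independent per-record membership scan
        for _, row in v.iterrows():
            t = h.years.index(row["year"])
            i = h.sites.index(row["site"])
            col_y = h.y[:, row["day"] - 1, t, i]
            expect = 1 if "sp1" in row["species_set"] else 0
            assert expect in col_y[col_y != MISSING]

    def test_day_without_visits_is_missing(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        h = build_detection_history(v, "sp1", STUDY, SEASON)
        assert (h.y[:, 0, 0, 1] == MISSING).all()   # siteB day 1: no visits
        assert h.nvisits[0, 0, 1] == 0

    def test_detection_sum_matches_visit_table(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        h = build_detection_history(v, "sp1", STUDY, SEASON)
        n_expected = sum("sp1" in s for s in v["species_set"])
        assert (h.y == 1).sum() == n_expected

    def test_unknown_focal_rejected(self, toy_records):
        v = build_visits(toy_records, SEASON, STUDY)
        with pytest.raises(ValueError, match="not in study list"):
            build_detection_history(v, "dodo", STUDY, SEASON)

    def test_save_load_round_trip(self, toy_records, tmp_path):
        v = build_visits(toy_records, SEASON, STUDY)
        h = build_detection_history(v, "sp1", STUDY, SEASON)
        h.save(tmp_path / "hist")
        h2 = DetectionHistory.load(tmp_path / "hist")
        np.testing.assert_array_equal(h.y, h2.y)
        np.testing.assert_array_equal(np.isnan(h.sll), np.isnan(h2.sll))
        np.testing.assert_allclose(h.pll, h2.pll)
        assert h2.sites == [str(s) for s in h.sites]


class TestSimulatorRoundTrip:
    def test_ingest_reconstructs_generator_arrays(self, tiny_dataset):
        """Uncapped ingest must reproduce the simulator's y and SLL exactly."""
        ds = tiny_dataset
        v = build_visits(ds.records, ds.season, ds.study_species)
        h = build_detection_history(v, ds.focal_species, ds.study_species,
                                    ds.season)
        assert h.y.shape == ds.y.shape
        np.testing.assert_array_equal(h.y, ds.y)
        np.testing.assert_array_equal(np.nan_to_num(h.sll),
                                      np.nan_to_num(ds.sll))

    def test_detection_count_preserved_after_capping(self, tiny_dataset):
        ds = tiny_dataset
        v = cap_visits(build_visits(ds.records, ds.season, ds.study_species), 5)
        h = build_detection_history(v, ds.focal_species, ds.study_species,
                                    ds.season, max_visits=5)
        n_in_table = sum(ds.focal_species in s for s in v["species_set"])
        assert h.n_detections() == n_in_table


def test_read_records_requires_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("species,site\nsp1,A\n")
    with pytest.raises(ValueError, match="observer"):
        read_records(p)
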