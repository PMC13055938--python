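"""Data-quality detectors: month arithmetic, discrepancies, lost contact,
post-death encounters, and exact agreement with generator designations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mortcord as mc

from conftest import cluster_of_person


class TestMonthDelta:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            ("2010-03-10", "2010-05-10", 2),
            ("2010-03-10", "2010-04-09", 0),
            ("2010-03-10", "2010-03-10", 0),
            ("2010-01-31", "2010-02-28", 0),   # incomplete final month
            ("2010-01-28", "2010-02-28", 1),
            ("2009-12-15", "2010-01-15", 1),
            ("2008-06-01", "2010-06-01", 24),
        ],
    )
    def test_examples(self, d1, d2, expected):
        assert mc.month_delta(d1, d2) == expected

    dates = st.dates(min_value=pd.Timestamp("2000-01-01").date(),
                     max_value=pd.Timestamp("2030-12-31").date())

    @given(dates, dates)
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_nonnegative(self, a, b):
        d = mc.month_delta(a, b)
        assert d == mc.month_delta(b, a)
        assert d >= 0
        if a == b:
            assert d == 0

    @given(dates, st.integers(min_value=0, max_value=60))
    @settings(max_examples=200, derandomize=True)
    def test_whole_month_shift_recovered(self, a, k):
        ts = pd.Timestamp(a)
        if ts.day <= 28:  # no day clamping, so the shift is exactly k months
            assert mc.month_delta(ts, mc.add_months(ts, k)) == k


def status_frame(rows):
    df = pd.DataFrame(rows)
    for c in ("death_date_A", "death_date_B", "death_date_S"):
        df[c] = pd.to_datetime(df.get(c))
    return df


class TestDateDiscrepancies:
    def test_toy_multiset_summary(self):
        # three A-B pairs 1, 2 and 20 whole months apart
        rows = [
            {"cluster_id": "c1", "death_date_A": "2010-01-10",
             "death_date_B": "2010-02-10"},
            {"cluster_id": "c2", "death_date_A": "2010-01-10",
             "death_date_B": "2010-03-10"},
            {"cluster_id": "c3", "death_date_A": "2010-01-10",
             "death_date_B": "2011-09-10"},
        ]
        flags, summary = mc.detect_date_discrepancies(status_frame(rows))
        assert summary["A-B"] == {"count": 3, "median": 2.0, "min": 1, "max": 20}
        assert sorted(flags["delta_months"]) == [1, 2, 20]

    def test_equal_dates_never_flagged(self):
        rows = [{"cluster_id": "c1", "death_date_A": "2010-01-10",
                 "death_date_B": "2010-01-10", "death_date_S": "2010-01-10"}]
        flags, summary = mc.detect_date_discrepancies(status_frame(rows))
        assert len(flags) == 0
        assert all(s["count"] == 0 for s in summary.values())

    def test_zero_threshold_flags_every_dual_dated_cluster(self):
        rows = [
            {"cluster_id": "c1", "death_date_A": "2010-01-10",
             "death_date_B": "2010-01-10"},
            {"cluster_id": "c2", "death_date_A": "2010-01-10",
             "death_date_S": "2010-01-12"},
        ]
        flags, _ = mc.detect_date_discrepancies(status_frame(rows),
                                                threshold_months=0)
        assert set(zip(flags["cluster_id"], flags["source_pair"])) == {
            ("c1", "A-B"), ("c2", "A-S")
        }

    def test_pair_requires_both_dates(self):
        rows = [{"cluster_id": "c1", "death_date_A": "2010-01-10"}]
        flags, _ = mc.detect_date_discrepancies(status_frame(rows), 0)
        assert len(flags) == 0


def _enc(rows):
    df = pd.DataFrame(rows, columns=["record_id", "source", "encounter_date"])
    df["encounter_date"] = pd.to_datetime(df["encounter_date"])
    return df


def _members(rows):
    return pd.DataFrame(rows, columns=["cluster_id", "source", "record_id",
                                       "matched"])


class TestLostContact:
    members = _members([
        ("c1", "SYSTEM_A", "a1", True),
        ("c1", "SYSTEM_B", "b1", True),
    ])

    def test_switch_after_window_is_flagged(self):
        enc = _enc([
            ("b1", "SYSTEM_B", "2010-01-15"),
            ("a1", "SYSTEM_A", "2012-03-01"),
        ])
        flags = mc.detect_lost_contact(enc, self.members)
        assert len(flags) == 1
        row = flags.iloc[0]
        assert (row["lost_from"], row["switched_to"]) == ("SYSTEM_B", "SYSTEM_A")
        assert row["last_visit_lost_source"] == pd.Timestamp("2010-01-15")
        assert row["first_visit_other_after_window"] == pd.Timestamp("2012-03-01")

    def test_other_visit_inside_window_does_not_count(self):
        enc = _enc([
            ("b1", "SYSTEM_B", "2010-01-15"),
            ("a1", "SYSTEM_A", "2010-06-01"),
        ])
        assert len(mc.detect_lost_contact(enc, self.members)) == 0

    def test_visit_exactly_at_window_boundary_not_after(self):
        enc = _enc([
            ("b1", "SYSTEM_B", "2010-01-15"),
            ("a1", "SYSTEM_A", "2011-01-15"),  # exactly 12 months later
        ])
        assert len(mc.detect_lost_contact(enc, self.members)) == 0

    def test_unmatched_clusters_excluded(self):
        members = _members([
            ("c1", "SYSTEM_A", "a1", False),
            ("c2", "SYSTEM_B", "b1", False),
        ])
        enc = _enc([
            ("b1", "SYSTEM_B", "2010-01-15"),
            ("a1", "SYSTEM_A", "2012-03-01"),
        ])
        assert len(mc.detect_lost_contact(enc, members)) == 0


class TestPostdeathEncounters:
    members = _members([
        ("c1", "SYSTEM_A", "a1", True),
        ("c1", "SYSTEM_B", "b1", True),
    ])

    def _run(self, enc_date):
        status = status_frame([{"cluster_id": "c1",
                                "death_date_A": "2010-01-01"}])
        enc = _enc([("b1", "SYSTEM_B", enc_date)])
        return mc.detect_postdeath_encounters(status, enc, self.members)

    def test_encounter_one_day_past_year_flagged(self):
        flags, rates = self._run("2011-01-02")
        assert len(flags) == 1
        assert flags.iloc[0]["death_source"] == "SYSTEM_A"
        assert flags.iloc[0]["encounter_source"] == "SYSTEM_B"
        assert rates["SYSTEM_A"] == {"flagged_deaths": 1, "deaths": 1, "rate": 1.0}

    def test_encounter_within_year_not_flagged(self):
        flags, rates = self._run("2010-12-31")
        assert len(flags) == 0
        assert rates["SYSTEM_A"]["flagged_deaths"] == 0

    def test_boundary_day_exactly_365_not_flagged(self):
        flags, _ = self._run("2011-01-01")
        assert len(flags) == 0


@pytest.fixture(scope="module")
def designated_cohort():
    counts = {"ABS": 40, "AB": 60, "AS": 50, "BS": 30,
              "A_only": 300, "B_only": 100, "S_only": 120, "none": 4300}
    cfg = mc.SyntheticConfig(
        n_matched=5000, category_counts=counts,
        death_rate_a=0, death_rate_b=0, death_rate_s=0,
        lost_contact_fraction=0.02, postdeath_encounter_fraction=0.1,
        date_shift_fraction=0.1, seed=29,
    )
    cohort = mc.generate_cohort(cfg)
    members, _ = mc.link_all(cohort.registry_a, cohort.registry_b,
                             cohort.ssadmf, cohort.crosswalk, "salt")
    status = mc.death_status_frame(members, cohort.registry_a,
                                   cohort.registry_b, cohort.ssadmf)
    return cohort, members, status


class TestDesignationExactness:
    def test_lost_contact_flags_equal_designated_set(self, designated_cohort):
        cohort, members, status = designated_cohort
        flags = mc.detect_lost_contact(cohort.encounters, members)
        cmap = cluster_of_person(members, cohort.truth)
        t = cohort.truth
        designated = {
            (cmap[uid], lost)
            for uid, lost in zip(t["person_uid"], t["lost_from"]) if lost
        }
        got = set(zip(flags["cluster_id"], flags["lost_from"]))
        assert got == designated
        assert len(designated) == round(0.02 * 5000)

    def test_date_discrepancy_flags_equal_designated_set(self, designated_cohort):
        cohort, members, status = designated_cohort
        flags, _ = mc.detect_date_discrepancies(status)
        cmap = cluster_of_person(members, cohort.truth)
        t = cohort.truth
        expected = set()
        letter = {"SYSTEM_A": "A", "SYSTEM_B": "B", "SSADMF": "S"}
        for r in t[t["shift_months"] != 0].itertuples():
            shifted = letter[r.shift_source]
            present = [l for l, d in (("A", r.death_date_a), ("B", r.death_date_b),
                                      ("S", r.death_date_s)) if not pd.isna(d)]
            for other in present:
                if other != shifted:
                    pair = "-".join(sorted([shifted, other]))
                    expected.add((cmap[r.person_uid], pair))
        got = set(zip(flags["cluster_id"], flags["source_pair"]))
        assert got == expected
        assert len(expected) > 0

    def test_postdeath_flags_equal_designated_set(self, designated_cohort):
        cohort, members, status = designated_cohort
        flags, rates = mc.detect_postdeath_encounters(
            status, cohort.encounters, members
        )
        cmap = cluster_of_person(members, cohort.truth)
        t = cohort.truth
        expected = set()
        for r in t[t["postdeath"]].itertuples():
            for src, d in (("SYSTEM_A", r.death_date_a),
                           ("SYSTEM_B", r.death_date_b),
                           ("SSADMF", r.death_date_s)):
                if not pd.isna(d):
                    expected.add((cmap[r.person_uid], src))
        got = set(zip(flags["cluster_id"], flags["death_source"]))
        assert got == expected
        assert len(expected) > 0
        # rate denominators come from each source's death total
        assert rates["SYSTEM_A"]["deaths"] == int(status["dead_A"].sum())
        assert rates["SSADMF"]["deaths"] == int(status["dead_S"].sum())

    def test_threshold_monotonicity(self, designated_cohort):
        cohort, members, status = designated_cohort
        dd_counts = [
            len(mc.detect_date_discrepancies(status, t)[0]) for t in (1, 2, 6, 24)
        ]
        assert dd_counts == sorted(dd_counts, reverse=True)
        pd_counts = [
            len(mc.detect_postdeath_encounters(status, cohort.encounters,
                                               members, t)[0])
            for t in (180, 365, 380, 1000)
        ]
        assert pd_counts == sorted(pd_counts, reverse=True)
        lc_counts = [
            len(mc.detect_lost_contact(cohort.encounters, members, w))
            for w in (6, 12, 13, 60)
        ]
        assert lc_counts == sorted(lc_counts, reverse=True)
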