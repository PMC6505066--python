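import numpy as np
import pandas as pd
import pytest

from oracle_utils import (oracle_bedded_partition, oracle_chain_partition,
                          oracle_ssh_partition, partition_from_groups,
                          random_stay_table)

from ehrdays import episodes
from ehrdays.config import default_specialty_config


@pytest.fixture(scope="module")
def spec_config():
    return default_specialty_config()


def prepared(stays_df, spec_config):
    return episodes.prepare_stays(stays_df, spec_config)


def make_stays(rows):
    return pd.DataFrame(rows, columns=["patient_id", "facility_id",
                                       "specialty_code", "admit", "discharge"])


class TestClassifySpecialty:
    def test_micu_is_acute_icu(self, spec_config):
        assert episodes.classify_specialty("MICU", spec_config) == (True, True)

    def test_nursing_home_is_nonacute(self, spec_config):
        assert episodes.classify_specialty("CLC", spec_config) == (False, False)

    def test_unknown_code_uses_default_and_warns(self, spec_config, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ehrdays.episodes"):
            result = episodes.classify_specialty("XENO-99", spec_config)
        assert result == (False, False)
        assert any("XENO-99" in r.message for r in caplog.records)


class TestBeddedStays:
    def test_single_stay_single_bedded(self, spec_config):
        stays = prepared(make_stays([("P1", "F1", "WARD",
                                      "2015-01-01 08:00", "2015-01-04 11:00")]), spec_config)
        bedded = episodes.build_bedded_stays(stays)
        assert len(bedded) == 1
        assert bedded.iloc[0]["n_stays"] == 1

    def test_exact_handoff_merges(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "MICU", "2015-01-01 08:00", "2015-01-03 11:00"),
            ("P1", "F1", "WARD", "2015-01-03 11:00", "2015-01-06 10:00"),
        ]), spec_config)
        assert len(episodes.build_bedded_stays(stays)) == 1

    def test_gapped_handoff_splits(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "MICU", "2015-01-01 08:00", "2015-01-03 11:00"),
            ("P1", "F1", "WARD", "2015-01-03 13:00", "2015-01-06 10:00"),
        ]), spec_config)
        assert len(episodes.build_bedded_stays(stays)) == 2

    def test_demo_trajectory_four_bedded_stays(self, demo_tables, spec_config):
        stays = prepared(demo_tables.specialty_transfers, spec_config)
        assert len(episodes.build_bedded_stays(stays)) == 4

    def test_random_instances_match_closure_oracle(self, spec_config):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            stays = prepared(random_stay_table(rng), spec_config)
            bedded = episodes.build_bedded_stays(stays)
            got = partition_from_groups(bedded, "stay_ids")
            want = oracle_bedded_partition(stays)
            assert got == want


class TestSingleSiteHospitalizations:
    def test_demo_two_sshs(self, demo_tables, spec_config):
        stays = prepared(demo_tables.specialty_transfers, spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        assert len(sshs) == 2
        spans = {(r.facility_id, str(r.admit_date.date()), str(r.discharge_date.date()))
                 for r in sshs.itertuples(index=False)}
        assert spans == {("FBC", "2014-03-01", "2014-03-03"),
                         ("FAA", "2014-03-03", "2014-03-10")}

    def test_nonacute_interruption_splits(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "WARD", "2015-01-01 08:00", "2015-01-03 11:00"),
            ("P1", "F1", "CLC", "2015-01-03 12:00", "2015-01-10 10:00"),
            ("P1", "F1", "WARD", "2015-01-10 12:00", "2015-01-12 09:00"),
        ]), spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        assert len(sshs) == 2
        assert partition_from_groups(sshs, "stay_ids") == oracle_ssh_partition(stays)

    def test_no_acute_stays_empty(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "CLC", "2015-01-01 08:00", "2015-01-09 10:00")]), spec_config)
        assert episodes.build_single_site_hospitalizations(stays).empty

    def test_censored_open_discharge_flagged(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "WARD", "2015-01-01 08:00", None)]), spec_config)
        sshs = episodes.build_single_site_hospitalizations(
            stays, observation_end="2015-01-05")
        assert sshs.iloc[0]["censored"]
        assert sshs.iloc[0]["discharge_date"] == pd.Timestamp("2015-01-05")

    def test_overlap_resolved_by_truncation(self, spec_config, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ehrdays.episodes"):
            stays = prepared(make_stays([
                ("P1", "F1", "WARD", "2015-01-01 08:00", "2015-01-06 11:00"),
                ("P1", "F1", "SURG", "2015-01-04 09:00", "2015-01-08 10:00"),
            ]), spec_config)
        assert stays["truncated"].any()
        first = stays.sort_values("admit").iloc[0]
        assert first["discharge"] == pd.Timestamp("2015-01-04 09:00")
        assert any("truncated" in r.message for r in caplog.records)

    def test_random_instances_match_closure_oracle(self, spec_config):
        rng = np.random.default_rng(99)
        for _ in range(60):
            stays = prepared(random_stay_table(rng), spec_config)
            sshs = episodes.build_single_site_hospitalizations(stays)
            if sshs.empty:
                assert not stays["acute"].any()
                continue
            assert partition_from_groups(sshs, "stay_ids") == oracle_ssh_partition(stays)


class TestLinking:
    def test_demo_one_acute_hospitalization(self, demo_tables, spec_config):
        stays = prepared(demo_tables.specialty_transfers, spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        sshs, hosps = episodes.link_acute_hospitalizations(sshs)
        assert len(hosps) == 1
        assert hosps.iloc[0]["admit_date"] == pd.Timestamp("2014-03-01")
        assert hosps.iloc[0]["discharge_date"] == pd.Timestamp("2014-03-10")

    def test_distant_sshs_stay_separate(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "WARD", "2015-01-01 08:00", "2015-01-03 11:00"),
            ("P1", "F2", "WARD", "2015-01-13 08:00", "2015-01-15 11:00"),
        ]), spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        _, hosps = episodes.link_acute_hospitalizations(sshs)
        assert len(hosps) == 2

    def test_demo_one_episode_of_care(self, demo_tables, spec_config):
        stays = prepared(demo_tables.specialty_transfers, spec_config)
        bedded = episodes.build_bedded_stays(stays)
        eps = episodes.build_episodes_of_care(bedded)
        assert len(eps) == 1
        assert eps.iloc[0]["n_bedded"] == 4

    def test_isolated_bedded_stay_is_one_episode(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "CLC", "2015-02-01 08:00", "2015-02-09 10:00")]), spec_config)
        bedded = episodes.build_bedded_stays(stays)
        assert len(episodes.build_episodes_of_care(bedded)) == 1

    def test_random_chaining_matches_closure_oracle(self, spec_config):
        rng = np.random.default_rng(7)
        for _ in range(60):
            stays = prepared(random_stay_table(rng), spec_config)
            sshs = episodes.build_single_site_hospitalizations(stays)
            sshs, hosps = episodes.link_acute_hospitalizations(sshs)
            if len(sshs):
                got = {frozenset(s.split(";")) for s in hosps["ssh_ids"]}
                want = oracle_chain_partition(sshs, "ssh_id", "admit_date", "discharge_date")
                assert got == want
            bedded = episodes.build_bedded_stays(stays)
            eps = episodes.build_episodes_of_care(bedded)
            got = {frozenset(s.split(";")) for s in eps["bedded_ids"]}
            bedded_dates = bedded.assign(start_date=bedded["start"].dt.normalize(),
                                         end_date=bedded["end"].dt.normalize())
            want = oracle_chain_partition(bedded_dates, "bedded_id", "start_date", "end_date")
            assert got == want


class TestExpansion:
    def test_demo_day_rows(self, demo_tables, spec_config):
        stays = prepared(demo_tables.specialty_transfers, spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        days = episodes.expand_patient_facility_days(sshs, stays)
        assert len(days) == 11
        d3 = days[days["date"] == "2014-03-03"]
        assert len(d3) == 2 and set(d3["facility_id"]) == {"FAA", "FBC"}
        d7 = days[days["date"] == "2014-03-07"]
        assert len(d7) == 1 and bool(d7.iloc[0]["icu_day"])
        d9 = days[days["date"] == "2014-03-09"]
        assert len(d9) == 1 and not bool(d9.iloc[0]["icu_day"])

    def test_one_day_ssh_one_row(self, spec_config):
        stays = prepared(make_stays([
            ("P1", "F1", "WARD", "2015-01-02 08:00", "2015-01-02 17:00")]), spec_config)
        sshs = episodes.build_single_site_hospitalizations(stays)
        days = episodes.expand_patient_facility_days(sshs, stays)
        assert len(days) == 1

    def test_row_count_conservation(self, spec_config):
        rng = np.random.default_rng(13)
        for _ in range(30):
            stays = prepared(random_stay_table(rng), spec_config)
            sshs = episodes.build_single_site_hospitalizations(stays)
            days = episodes.expand_patient_facility_days(sshs, stays)
            if sshs.empty:
                assert days.empty
                continue
            spans = ((sshs["discharge_date"] - sshs["admit_date"]).dt.days + 1).sum()
            assert len(days) == spans
            assert not days.duplicated(["patient_id", "facility_id", "date"]).any()

    def test_unrelated_patient_does_not_change_output(self, spec_config):
        rows_a = [("PA", "F1", "MICU", "2015-01-01 08:00", "2015-01-05 11:00"),
                  ("PA", "F2", "WARD", "2015-01-05 13:00", "2015-01-09 10:00")]
        rows_b = [("PB", "F1", "WARD", "2015-01-02 09:00", "2015-01-20 11:00")]
        solo = prepared(make_stays(rows_a), spec_config)
        both = prepared(make_stays(rows_a + rows_b), spec_config)
        for build in (episodes.build_single_site_hospitalizations,):
            a = build(solo)
            ab = build(both)
            ab_a = ab[ab["patient_id"] == "PA"].reset_index(drop=True)
            pd.testing.assert_frame_equal(
                a.drop(columns="stay_ids"), ab_a.drop(columns="stay_ids"))


class TestOutcomes:
    def _ssh(self, rows):
        df = pd.DataFrame(rows, columns=["ssh_id", "patient_id", "facility_id",
                                         "admit_date", "discharge_date", "censored"])
        df["admit_date"] = pd.to_datetime(df["admit_date"])
        df["discharge_date"] = pd.to_datetime(df["discharge_date"])
        return df

    def test_death_on_discharge_date_counts_both_ways(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-05", False)])
        deaths = pd.DataFrame({"patient_id": ["P1"], "death_date": ["2015-01-05"]})
        out, rejected = episodes.compute_outcomes(sshs, deaths)
        assert rejected.empty
        assert bool(out.iloc[0]["in_hospital_mortality"])
        assert bool(out.iloc[0]["mortality_30d"])

    def test_death_after_discharge_within_30_days_of_admission(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-10", False)])
        deaths = pd.DataFrame({"patient_id": ["P1"], "death_date": ["2015-01-21"]})
        out, _ = episodes.compute_outcomes(sshs, deaths)
        assert not bool(out.iloc[0]["in_hospital_mortality"])
        assert bool(out.iloc[0]["mortality_30d"])  # day 20 from admission

    def test_death_beyond_30_days(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-10", False)])
        deaths = pd.DataFrame({"patient_id": ["P1"], "death_date": ["2015-03-01"]})
        out, _ = episodes.compute_outcomes(sshs, deaths)
        assert not bool(out.iloc[0]["mortality_30d"])

    def test_in_hospital_death_excluded_from_readmission_denominator(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-05", False),
                          ("S2", "P1", "F1", "2015-01-20", "2015-01-25", False)])
        deaths = pd.DataFrame({"patient_id": ["P1"], "death_date": ["2015-01-25"]})
        out, _ = episodes.compute_outcomes(sshs, deaths)
        first = out[out["ssh_id"] == "S1"].iloc[0]
        assert bool(first["readmit_30d"])  # live discharge, readmitted day 19
        second = out[out["ssh_id"] == "S2"].iloc[0]
        assert pd.isna(second["readmit_30d"])  # died in hospital

    def test_readmission_within_window(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-05", False),
                          ("S2", "P1", "F2", "2015-01-20", "2015-01-25", False)])
        sshs["hosp_id"] = ["H1", "H2"]
        out, _ = episodes.compute_outcomes(sshs, None)
        assert bool(out[out["ssh_id"] == "S1"].iloc[0]["readmit_30d"])
        assert not bool(out[out["ssh_id"] == "S2"].iloc[0]["readmit_30d"])

    def test_transfer_is_not_a_readmission(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-01-01", "2015-01-05", False),
                          ("S2", "P1", "F2", "2015-01-05", "2015-01-09", False)])
        sshs["hosp_id"] = ["H1", "H1"]
        out, _ = episodes.compute_outcomes(sshs, None)
        assert not bool(out[out["ssh_id"] == "S1"].iloc[0]["readmit_30d"])

    def test_death_before_admission_rejected(self):
        sshs = self._ssh([("S1", "P1", "F1", "2015-02-01", "2015-02-05", False)])
        deaths = pd.DataFrame({"patient_id": ["P1"], "death_date": ["2015-01-01"]})
        out, rejected = episodes.compute_outcomes(sshs, deaths)
        assert len(rejected) == 1
        assert not bool(out.iloc[0]["mortality_30d"])
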