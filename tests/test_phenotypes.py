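import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import cardio_score, coag_score, liver_score, renal_score

from ehrdays import phenotypes
from ehrdays.config import (default_ase_config, default_code_lists,
                            default_lexicon_config, default_risk_config,
                            default_sofa_config)
from ehrdays.errors import UnsupportedOperationError

KEY = ["patient_id", "facility_id", "date"]


@pytest.fixture(scope="module")
def sofa_cfg():
    return default_sofa_config()


@pytest.fixture(scope="module")
def lexicon():
    return default_lexicon_config()


@pytest.fixture(scope="module")
def code_lists():
    return default_code_lists()


def day_key(date="2015-01-02"):
    return {"patient_id": "P1", "facility_id": "F1", "date": pd.Timestamp(date)}


def score_one(sofa_cfg, lexicon, platelets=None, bilirubin=None, creatinine=None,
              map_low=None, pressors=()):
    phys = pd.DataFrame([{**day_key(),
                          "platelets_low": platelets, "bilirubin_high": bilirubin,
                          "creatinine_high": creatinine, "map_low": map_low}])
    med = pd.DataFrame([{**day_key(),
                         **{f"rx_{d}": (d in pressors) for d in lexicon["drugs"]}}])
    out = phenotypes.sofa_component_scores(phys, med, sofa_cfg, lexicon)
    row = out.iloc[0]
    return {c: row[f"sofa_{c}"] for c in phenotypes.SOFA_COMPONENTS}


class TestSofaScores:
    def test_all_normal_scores_zero(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, platelets=250, bilirubin=0.8,
                      creatinine=0.9, map_low=85)
        assert (s["coagulation"], s["liver"], s["cardiovascular"], s["renal"]) == (0, 0, 0, 0)

    def test_platelet_45_scores_3(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, platelets=45, map_low=85)
        assert s["coagulation"] == 3

    def test_pressor_overrides_normal_map(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, map_low=80, pressors=("norepinephrine",))
        assert s["cardiovascular"] >= 2

    def test_dobutamine_tier_two(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, map_low=80, pressors=("dobutamine",))
        assert s["cardiovascular"] == 2

    def test_missing_inputs_stay_missing(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, map_low=85)
        assert pd.isna(s["coagulation"]) and pd.isna(s["liver"]) and pd.isna(s["renal"])
        assert s["cardiovascular"] == 0

    def test_no_map_no_pressor_cardio_missing(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, platelets=200)
        assert pd.isna(s["cardiovascular"])

    def test_pressor_with_missing_map_scores_tier(self, sofa_cfg, lexicon):
        s = score_one(sofa_cfg, lexicon, pressors=("vasopressin",))
        assert s["cardiovascular"] == 3

    @settings(max_examples=150, deadline=None)
    @given(platelets=st.one_of(st.none(), st.floats(1, 500)),
           bilirubin=st.one_of(st.none(), st.floats(0.1, 30)),
           creatinine=st.one_of(st.none(), st.floats(0.1, 12)),
           map_low=st.one_of(st.none(), st.floats(30, 120)),
           pressors=st.sets(st.sampled_from(["norepinephrine", "dobutamine",
                                             "vasopressin", "milrinone"]), max_size=2))
    def test_agreement_with_ladder_oracle(self, sofa_cfg, lexicon, platelets,
                                          bilirubin, creatinine, map_low, pressors):
        s = score_one(sofa_cfg, lexicon, platelets=platelets, bilirubin=bilirubin,
                      creatinine=creatinine, map_low=map_low, pressors=tuple(pressors))
        tiers = [lexicon["drugs"][p]["sofa_tier"] for p in pressors]
        for got, want in [(s["coagulation"], coag_score(platelets)),
                          (s["liver"], liver_score(bilirubin)),
                          (s["renal"], renal_score(creatinine)),
                          (s["cardiovascular"], cardio_score(map_low, tiers))]:
            if want is None:
                assert pd.isna(got)
            else:
                assert got == want

    @settings(max_examples=80, deadline=None)
    @given(platelets=st.floats(5, 400), worse_by=st.floats(0.1, 100))
    def test_monotonic_in_platelets(self, sofa_cfg, lexicon, platelets, worse_by):
        base = score_one(sofa_cfg, lexicon, platelets=platelets, map_low=85)
        worse = score_one(sofa_cfg, lexicon, platelets=max(platelets - worse_by, 0.5),
                          map_low=85)
        assert worse["coagulation"] >= base["coagulation"]

    @settings(max_examples=80, deadline=None)
    @given(value=st.floats(0.2, 10), worse_by=st.floats(0.1, 15))
    def test_monotonic_in_bilirubin_and_creatinine(self, sofa_cfg, lexicon, value, worse_by):
        base = score_one(sofa_cfg, lexicon, bilirubin=value, creatinine=value, map_low=85)
        worse = score_one(sofa_cfg, lexicon, bilirubin=value + worse_by,
                          creatinine=value + worse_by, map_low=85)
        assert worse["liver"] >= base["liver"]
        assert worse["renal"] >= base["renal"]

    @settings(max_examples=60, deadline=None)
    @given(map_low=st.floats(40, 110))
    def test_adding_pressor_never_decreases_cardio(self, sofa_cfg, lexicon, map_low):
        base = score_one(sofa_cfg, lexicon, map_low=map_low)
        worse = score_one(sofa_cfg, lexicon, map_low=map_low, pressors=("norepinephrine",))
        assert worse["cardiovascular"] >= base["cardiovascular"]


class TestOrganFailure:
    def test_three_and_four_flag(self, sofa_cfg, lexicon):
        scores = pd.DataFrame([
            {**day_key("2015-01-01"), "sofa_coagulation": 3, "sofa_liver": 2,
             "sofa_cardiovascular": 4, "sofa_renal": pd.NA},
        ]).astype({f"sofa_{c}": "Int64" for c in phenotypes.SOFA_COMPONENTS})
        flags, totals = phenotypes.organ_failure_days(scores)
        row = flags.iloc[0]
        assert row["failure_coagulation"] and row["failure_cardiovascular"]
        assert not row["failure_liver"] and not row["failure_renal"]
        assert totals == {"coagulation": 1, "liver": 0, "cardiovascular": 1, "renal": 0}

    def test_totals_equal_full_scan(self, cohort_build):
        scores = cohort_build["scores"]
        _, totals = phenotypes.organ_failure_days(scores)
        for comp in phenotypes.SOFA_COMPONENTS:
            brute = sum(1 for v in scores[f"sofa_{comp}"] if pd.notna(v) and v in (3, 4))
            assert totals[comp] == brute


def ssh_frame(rows):
    df = pd.DataFrame(rows, columns=["ssh_id", "patient_id", "facility_id",
                                     "admit_date", "discharge_date"])
    df["admit_date"] = pd.to_datetime(df["admit_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def code_frame(rows):
    return pd.DataFrame(rows, columns=["ssh_id", "patient_id", "facility_id", "code",
                                       "icd_version", "code_type", "position"])


class TestAngus:
    SSHS = ssh_frame([("S1", "P1", "F1", "2015-01-01", "2015-01-08")])

    def test_explicit_code_alone(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "99592", "9", "dx", 1)])
        out, bad = phenotypes.angus_sepsis(codes, self.SSHS, code_lists)
        assert bool(out.iloc[0]["angus_sepsis"]) and bad.empty

    def test_infection_alone_is_false(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "486", "9", "dx", 1)])
        out, _ = phenotypes.angus_sepsis(codes, self.SSHS, code_lists)
        assert not bool(out.iloc[0]["angus_sepsis"])

    def test_infection_plus_organ_dysfunction(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "486", "9", "dx", 1),
                            ("S1", "P1", "F1", "5849", "9", "dx", 2)])
        out, _ = phenotypes.angus_sepsis(codes, self.SSHS, code_lists)
        assert bool(out.iloc[0]["angus_sepsis"])

    def test_icd10_explicit(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "R6520", "10", "dx", 1)])
        out, _ = phenotypes.angus_sepsis(codes, self.SSHS, code_lists)
        assert bool(out.iloc[0]["angus_sepsis"])

    def test_unknown_version_reported(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "99592", "11", "dx", 1)])
        out, bad = phenotypes.angus_sepsis(codes, self.SSHS, code_lists)
        assert len(bad) == 1
        assert not bool(out.iloc[0]["angus_sepsis"])


class TestGemConversion:
    GEM = pd.DataFrame({
        "source": ["0380", "0380", "A4189", "A419", "99591"],
        "target": ["A4101", "A4102", "0380", "0389", "R652"],
        "direction": ["forward", "forward", "backward", "backward", "forward"],
    })

    def test_union_of_both_directions_hand_computed(self):
        out, unmapped = phenotypes.convert_code_lists(["0380"], self.GEM)
        assert out == ["A4101", "A4102", "A4189"]
        assert unmapped == []

    def test_duplicate_appears_once(self):
        gem = pd.concat([self.GEM, pd.DataFrame({"source": ["0380"], "target": ["A4189"],
                                                 "direction": ["forward"]})])
        out, _ = phenotypes.convert_code_lists(["0380"], gem)
        assert out == ["A4101", "A4102", "A4189"]

    def test_exclusion_applied_last(self):
        out, _ = phenotypes.convert_code_lists(["0380"], self.GEM, exclusions=["A4102"])
        assert out == ["A4101", "A4189"]

    def test_unmapped_reported(self):
        out, unmapped = phenotypes.convert_code_lists(["0380", "9999"], self.GEM)
        assert unmapped == ["9999"]

    def test_dot_normalization(self):
        out, _ = phenotypes.convert_code_lists(["038.0"], self.GEM)
        assert out == ["A4101", "A4102", "A4189"]


def build_ase_inputs(culture_days, abx_days, vaso_days, span=("2015-01-01", "2015-01-10"),
                     shift_days=0):
    shift = pd.Timedelta(days=shift_days)
    lo, hi = pd.Timestamp(span[0]) + shift, pd.Timestamp(span[1]) + shift
    sshs = ssh_frame([("S1", "P1", "F1", lo, hi)])
    dates = pd.date_range(lo, hi)
    days = pd.DataFrame({"patient_id": "P1", "facility_id": "F1",
                         "date": dates, "ssh_id": "S1"})
    ind = days[KEY].copy()
    abx = {pd.Timestamp(d) + shift for d in abx_days}
    vaso = {pd.Timestamp(d) + shift for d in vaso_days}
    ind["abx_systemic"] = [d in abx for d in dates]
    ind["any_vasopressor"] = [d in vaso for d in dates]
    cultures = pd.DataFrame({"patient_id": "P1", "facility_id": "F1",
                             "date": [pd.Timestamp(c) + shift for c in culture_days]})
    phys = days[KEY].copy()
    return sshs, days, cultures, ind, phys


class TestCdcAse:
    def run(self, *args, **kwargs):
        sshs, days, cultures, ind, phys = build_ase_inputs(*args, **kwargs)
        return phenotypes.cdc_ase_sepsis(sshs, days, cultures, ind, phys,
                                         None, default_ase_config())

    def test_no_culture_is_false(self):
        out = self.run([], ["2015-01-02", "2015-01-03", "2015-01-04", "2015-01-05"],
                       ["2015-01-03"])
        assert not bool(out.iloc[0]["cdc_ase"])

    def test_textbook_positive(self):
        out = self.run(["2015-01-02"],
                       [f"2015-01-0{d}" for d in range(2, 7)], ["2015-01-03"])
        assert bool(out.iloc[0]["cdc_ase"])
        assert out.iloc[0]["ase_culture_date"] == pd.Timestamp("2015-01-02")

    def test_short_antibiotic_run_fails(self):
        out = self.run(["2015-01-02"], ["2015-01-02", "2015-01-03"], ["2015-01-03"])
        assert not bool(out.iloc[0]["cdc_ase"])

    def test_run_truncated_by_discharge_qualifies(self):
        out = self.run(["2015-01-09"], ["2015-01-09", "2015-01-10"], ["2015-01-09"])
        assert bool(out.iloc[0]["cdc_ase"])

    def test_culture_outside_window_of_antibiotics(self):
        out = self.run(["2015-01-01"],
                       ["2015-01-06", "2015-01-07", "2015-01-08", "2015-01-09"],
                       ["2015-01-01"])
        assert not bool(out.iloc[0]["cdc_ase"])

    def test_no_organ_dysfunction_is_false(self):
        out = self.run(["2015-01-02"], [f"2015-01-0{d}" for d in range(2, 7)], [])
        assert not bool(out.iloc[0]["cdc_ase"])

    def test_vasopressor_outside_window_does_not_count(self):
        out = self.run(["2015-01-02"],
                       [f"2015-01-0{d}" for d in range(2, 8)], ["2015-01-07"])
        assert not bool(out.iloc[0]["cdc_ase"])

    @pytest.mark.parametrize("shift", [-10, 0, 17])
    def test_window_shift_invariance(self, shift):
        args = (["2015-02-02"],
                ["2015-02-02", "2015-02-03", "2015-02-04", "2015-02-05"],
                ["2015-02-03"])
        base = self.run(*args, span=("2015-02-01", "2015-02-10"))
        shifted = self.run(*args, span=("2015-02-01", "2015-02-10"), shift_days=shift)
        assert bool(base.iloc[0]["cdc_ase"]) == bool(shifted.iloc[0]["cdc_ase"])

    def test_lab_criterion_platelet_drop(self):
        sshs, days, cultures, ind, phys = build_ase_inputs(
            ["2015-01-03"], [f"2015-01-0{d}" for d in range(3, 8)], [])
        phys = phys.copy()
        phys["platelets_low"] = [220.0, 210.0, 60.0, 200.0, 205.0,
                                 207.0, 203.0, 201.0, 202.0, 204.0]
        phys["platelets_high"] = [230.0, 215.0, 80.0, 210.0, 210.0,
                                  212.0, 208.0, 206.0, 207.0, 209.0]
        out = phenotypes.cdc_ase_sepsis(sshs, days, cultures, ind, phys,
                                        None, default_ase_config())
        assert bool(out.iloc[0]["cdc_ase"])

    def test_ventilation_counts_as_dysfunction(self):
        sshs, days, cultures, ind, phys = build_ase_inputs(
            ["2015-01-02"], [f"2015-01-0{d}" for d in range(2, 7)], [])
        vent = pd.DataFrame({"ssh_id": ["S1"], "mechanical_ventilation": [True]})
        out = phenotypes.cdc_ase_sepsis(sshs, days, cultures, ind, phys,
                                        vent, default_ase_config())
        assert bool(out.iloc[0]["cdc_ase"])


class TestVentilation:
    SSHS = ssh_frame([("S1", "P1", "F1", "2015-01-01", "2015-01-08")])

    def test_procedure_code_detected(self, code_lists):
        codes = code_frame([("S1", "P1", "F1", "9670", "9", "proc", 1)])
        out = phenotypes.detect_mechanical_ventilation(codes, self.SSHS, code_lists)
        assert bool(out.iloc[0]["mechanical_ventilation"])

    def test_no_codes_false(self, code_lists):
        out = phenotypes.detect_mechanical_ventilation(
            code_frame([]), self.SSHS, code_lists)
        assert not bool(out.iloc[0]["mechanical_ventilation"])

    def test_day_level_query_unsupported(self, code_lists):
        with pytest.raises(UnsupportedOperationError):
            phenotypes.detect_mechanical_ventilation(
                code_frame([]), self.SSHS, code_lists, level="day")


class TestRiskComponents:
    SSHS = ssh_frame([("S1", "P1", "F1", "2015-01-01", "2015-01-08")])
    PATIENTS = pd.DataFrame({"patient_id": ["P1"], "age": [66]})

    def test_age_and_empty_flags(self):
        out = phenotypes.assemble_risk_components(
            self.SSHS, self.PATIENTS, code_frame([]), pd.DataFrame(),
            default_risk_config())
        row = out.iloc[0]
        assert row["age"] == 66
        cm_cols = [c for c in out.columns if c.startswith("cm_")]
        assert len(cm_cols) == 30
        assert not any(row[c] for c in cm_cols)

    def test_diabetes_code_sets_flag(self):
        codes = code_frame([("S1", "P1", "F1", "E119", "10", "dx", 2)])
        out = phenotypes.assemble_risk_components(
            self.SSHS, self.PATIENTS, codes, pd.DataFrame(), default_risk_config())
        assert bool(out.iloc[0]["cm_diabetes_uncomplicated"])

    def test_admission_dx_category(self):
        codes = code_frame([("S1", "P1", "F1", "A419", "10", "dx", 1)])
        out = phenotypes.assemble_risk_components(
            self.SSHS, self.PATIENTS, codes, pd.DataFrame(), default_risk_config())
        assert out.iloc[0]["admission_dx_category"] == "infectious"

    def test_composite_request_unsupported(self):
        with pytest.raises(UnsupportedOperationError):
            phenotypes.assemble_risk_components(
                self.SSHS, self.PATIENTS, code_frame([]), pd.DataFrame(),
                default_risk_config(), composite=True)
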